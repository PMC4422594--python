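"""Pipeline configuration and per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .features import DEFAULT_BANDS, BandDefinition
from .recording import DEFAULT_MONTAGE, DEFAULT_RATE

__all__ = ["PipelineConfig", "derive_seed", "INDEX_NAMES"]

#: The three model-based indices, each discriminated against neutral.
INDEX_NAMES = ("happiness", "surprise", "attention")


def derive_seed(base: int, *keys: str | int) -> int:
    """Derive a reproducible sub-seed (< 2^31) from a base seed and keys.

    String keys hash through CRC-32, so the derivation is stable across
    processes and platforms.
    """
    ints = tuple(
        k if isinstance(k, int) else zlib.crc32(str(k).encode()) for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, with study defaults.

    Defaults follow the calibration design: 14-channel montage at 128 Hz,
    0.5-100 Hz band-pass (upper edge clamped below Nyquist at run time),
    quarter-second windows, six bands (84 features), log-power features,
    tenfold CV, and the 2p - 1 index normalization with a 0.5 peak
    threshold.
    """

    montage: tuple[str, ...] = DEFAULT_MONTAGE
    rate: float = DEFAULT_RATE
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    window_s: float = 0.25
    filter_low: float = 0.5
    filter_high: float = 100.0
    log_features: bool = True
    cv_folds: int = 10
    seed: int = 0
    ridge: float | None = None
    peak_threshold: float = 0.5
    index_names: tuple[str, ...] = INDEX_NAMES
    data_dir: str = "data"
    out_dir: str = "out"

    def __post_init__(self) -> None:
        for name in ("rate", "window_s", "filter_low", "filter_high", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1 < self.peak_threshold < 1:
            raise ValueError("peak_threshold must lie in (-1, 1)")

    def stage_seed(self, *keys: str | int) -> int:
        return derive_seed(self.seed, *keys)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "bands" in doc:
            doc["bands"] = tuple(
                BandDefinition(b["name"], b["low"], b["high"]) for b in doc["bands"]
            )
        if "montage" in doc:
            doc["montage"] = tuple(doc["montage"])
        if "index_names" in doc:
            doc["index_names"] = tuple(doc["index_names"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> Path:
        doc = asdict(self)
        doc["montage"] = list(self.montage)
        doc["index_names"] = list(self.index_names)
        doc["bands"] = [
            {"name": b.name, "low": b.low, "high": b.high} for b in self.bands
        ]
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path
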