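"""Readers and writers for recordings, features, models, and result tables.

Recordings travel as CSV (UTF-8, comma-separated, header
``time_s,<CH1>,...``) or EDF (read-only, via :mod:`mne` when installed).
Derived artifacts are TSV with fixed float formatting so identical runs
produce byte-identical files; the discriminant model serializes to JSON
with everything scoring needs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .flda import FLDAModel
from .recording import EEGRecording
from .scoring import ClipSummary, IndexSeries, PeakWindow, summary_table
from .selection import SelectionResult

__all__ = [
    "read_recording",
    "write_recording",
    "read_features",
    "write_features",
    "write_selection",
    "read_model",
    "write_model",
    "write_index_series",
    "write_summaries",
    "write_peaks",
    "write_ground_truth",
    "read_ground_truth",
]

FLOAT_FMT = "%.10g"
#: Maximum tolerated relative jitter of CSV timestamps (1 ppm).
TIME_JITTER = 1e-6


def _float_str(x: float) -> str:
    return FLOAT_FMT % x


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    *,
    montage: Sequence[str] | None = None,
    subject_id: str = "",
    session_label: str = "",
) -> EEGRecording:
    """Read a recording from CSV or EDF.

    CSV files need a ``time_s`` column followed by one column per channel.
    When ``montage`` is given, channels are reordered to match it and a
    missing channel raises an error naming it. The sampling rate is
    inferred from the timestamps, which must be regular to within 1 ppm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.columns[0] != "time_s":
            raise ValueError(
                f"{path}: first CSV column must be 'time_s', got "
                f"{df.columns[0]!r}"
            )
        labels = list(df.columns[1:])
        times = df["time_s"].to_numpy(dtype=float)
        if len(times) < 2:
            raise ValueError(f"{path}: need at least 2 samples")
        dt = np.diff(times)
        if np.any(np.abs(dt - dt.mean()) > TIME_JITTER * max(times[-1], 1.0)):
            raise ValueError(f"{path}: irregular timestamps (beyond 1 ppm)")
        rate = 1.0 / dt.mean()
        data = df[labels].to_numpy(dtype=float).T
    elif fmt == "edf":
        try:
            import mne
        except ImportError:
            raise ImportError(
                "reading EDF requires the optional 'mne' dependency"
            ) from None
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        labels = list(raw.ch_names)
        rate = float(raw.info["sfreq"])
        data = raw.get_data() * 1e6  # volts -> microvolts
    else:
        raise ValueError(f"unknown recording format {fmt!r}")

    if montage is not None:
        missing = [ch for ch in montage if ch not in labels]
        if missing:
            raise ValueError(
                f"{path}: missing montage channel(s) {missing}; file has "
                f"{labels}"
            )
        order = [labels.index(ch) for ch in montage]
        data = data[order]
        labels = list(montage)
    # round to remove timestamp quantization error (e.g. 1/128 s grid)
    rate = round(rate, 6)
    return EEGRecording(
        subject_id=subject_id or path.stem,
        session_label=session_label or path.stem,
        montage=tuple(labels),
        rate=rate,
        data=data,
    )


def write_recording(rec: EEGRecording, path: str | Path, fmt: str = "csv") -> Path:
    """Write a recording as CSV (``time_s`` + one column per channel)."""
    path = Path(path)
    if fmt != "csv":
        raise ValueError(
            f"unsupported write format {fmt!r}: recordings are written as "
            "CSV (no EDF export backend is available)"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "time_s," + ",".join(rec.montage)
    table = np.column_stack([rec.times, rec.data.T])
    np.savetxt(
        path, table, delimiter=",", header=header, comments="", fmt=FLOAT_FMT
    )
    return path


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    """Serialize a feature matrix as TSV (window_start_s + CHANNEL_band columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fm.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_features(
    path: str | Path, *, log_scale: bool = True,
    subject_id: str = "", session_label: str = "",
) -> FeatureMatrix:
    """Read a feature TSV written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "window_start_s":
        raise ValueError(f"{path}: first column must be 'window_start_s'")
    names = list(df.columns[1:])
    index = tuple(tuple(n.split("_", 1)) for n in names)
    return FeatureMatrix(
        feature_index=index,  # type: ignore[arg-type]
        values=df[names].to_numpy(dtype=float),
        window_start_times=df["window_start_s"].to_numpy(dtype=float),
        log_scale=log_scale,
        subject_id=subject_id,
        session_label=session_label,
    )


def write_selection(result: SelectionResult, path: str | Path) -> Path:
    """Write chosen features as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_table().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "subject_id": result.subject_id,
        "index_name": result.index_name,
        "folds": result.folds,
        "seed": result.seed,
        "final_cv_accuracy": result.final_cv_accuracy,
        "n_chosen": result.n_chosen,
        "chosen_names": list(result.chosen_names),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    return path


def write_model(model: FLDAModel, path: str | Path) -> Path:
    """Serialize a fitted discriminant to JSON (sufficient for scoring)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "w": model.w.tolist(),
        "class_means": model.class_means.tolist(),
        "grand_mean": model.grand_mean.tolist(),
        "proj_means": model.proj_means.tolist(),
        "proj_vars": model.proj_vars.tolist(),
        "ridge": model.ridge,
        "priors": list(model.priors),
        "pooled_variance": model.pooled_variance,
        "feature_names": list(model.feature_names or []),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_model(path: str | Path) -> FLDAModel:
    """Load a discriminant serialized by :func:`write_model`.

    Scatter matrices are not stored; they are set to zero placeholders as
    scoring only needs the projection and projected class statistics.
    """
    doc = json.loads(Path(path).read_text())
    w = np.asarray(doc["w"], dtype=float)
    d = w.shape[0]
    return FLDAModel(
        w=w,
        class_means=np.asarray(doc["class_means"], dtype=float),
        grand_mean=np.asarray(doc["grand_mean"], dtype=float),
        S_B=np.zeros((d, d)),
        S_W=np.zeros((d, d)),
        proj_means=np.asarray(doc["proj_means"], dtype=float),
        proj_vars=np.asarray(doc["proj_vars"], dtype=float),
        ridge=float(doc["ridge"]),
        priors=tuple(doc["priors"]),  # type: ignore[arg-type]
        pooled_variance=bool(doc["pooled_variance"]),
        feature_names=tuple(doc["feature_names"]) or None,
    )


def write_index_series(series: IndexSeries, path: str | Path) -> Path:
    """IndexSeries TSV: window_start_s, value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def write_summaries(summaries: Sequence[ClipSummary], path: str | Path) -> Path:
    """ClipSummary TSV: index, clip, n_subjects, mean, sd, rank."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary_table(summaries).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    return path


def write_peaks(peaks: Sequence[PeakWindow], path: str | Path) -> Path:
    """PeakWindow TSV: start_s, end_s, peak."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [{"start_s": p.start_s, "end_s": p.end_s, "peak": p.peak} for p in peaks],
        columns=["start_s", "end_s", "peak"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def write_ground_truth(
    truth: np.ndarray, path: str | Path, window_s: float = 0.25
) -> Path:
    """Ground-truth TSV: window_start_s, intensity."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    starts = np.arange(len(truth)) * window_s
    df = pd.DataFrame({"window_start_s": starts, "intensity": truth})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_ground_truth(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["intensity"].to_numpy(dtype=float)
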