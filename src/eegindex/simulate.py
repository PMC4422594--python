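"""Synthetic EEG sessions with known ground truth.

Real calibration and commercial-viewing EEG is not redistributable, so the
pipeline is exercised on simulated sessions that emulate the study design:
a broadband 1/f^alpha Gaussian background per channel, plus additive
band-limited oscillations planted at named (channel, band) cells whose
amplitude is calibrated so the band power equals the neutral expectation
times a configured multiplier. Commercial sessions modulate the planted
amplitude over time with a state-intensity trajectory in [0, 1] and return
the per-window trajectory as ground truth.

Everything is driven by a single integer seed: each (seed, condition) pair
regenerates bit-identical sample arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal

from .features import DEFAULT_BANDS, BandDefinition
from .recording import DEFAULT_MONTAGE, DEFAULT_RATE, EEGRecording

__all__ = [
    "SyntheticConfig",
    "CONDITIONS",
    "DEFAULT_PLANTED_EFFECTS",
    "generate_session",
    "generate_commercial",
    "piecewise_linear",
]

#: Session labels the generator understands.
CONDITIONS = ("neutral", "happiness", "surprise", "attention", "commercial")

#: Default planted (channel, band, power multiplier) per target condition.
#: The topography follows the feature sites most associated with each index:
#: happiness in high-frequency right fronto-central/temporal activity,
#: surprise in prefrontal/temporal/occipital gamma and high beta, attention
#: in left-prefrontal high beta.
DEFAULT_PLANTED_EFFECTS: dict[str, tuple[tuple[str, str, float], ...]] = {
    "happiness": (("FC5", "high_beta", 2.5), ("T8", "gamma", 2.5)),
    "surprise": (
        ("AF3", "gamma", 2.5),
        ("T7", "high_beta", 2.5),
        ("O2", "gamma", 2.5),
    ),
    "attention": (("AF3", "high_beta", 2.5),),
}

Trajectory = Callable[[np.ndarray], np.ndarray]


def piecewise_linear(points: Sequence[tuple[float, float]]) -> Trajectory:
    """Build a piecewise-linear trajectory from (time_s, intensity) breakpoints.

    The returned callable maps times to intensities in [0, 1] and raises
    ``ValueError`` when evaluated outside the breakpoint span, so a
    trajectory that does not cover the whole session fails loudly.
    """
    pts = sorted((float(t), float(v)) for t, v in points)
    if len(pts) < 2:
        raise ValueError("need at least two breakpoints")
    ts = np.array([p[0] for p in pts])
    vs = np.array([p[1] for p in pts])
    if vs.min() < 0 or vs.max() > 1:
        raise ValueError("trajectory intensities must lie in [0, 1]")

    def traj(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < ts[0] - 1e-9 or t.max() > ts[-1] + 1e-9):
            raise ValueError(
                f"trajectory defined on [{ts[0]}, {ts[-1]}] s but evaluated "
                f"at [{t.min():.6g}, {t.max():.6g}] s"
            )
        return np.interp(t, ts, vs)

    return traj


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic-session generator.

    ``planted_effects`` maps each target condition to (channel, band,
    multiplier) triples: under that condition the expected band power at
    the named cell is ``multiplier`` times its neutral expectation.
    Multipliers must be >= 1.
    """

    montage: tuple[str, ...] = DEFAULT_MONTAGE
    rate: float = DEFAULT_RATE
    session_length: float = 40.0
    planted_effects: Mapping[str, tuple[tuple[str, str, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS)
    )
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    noise_exponent: float = 1.0
    amplitude_uv: float = 20.0
    trajectory: Trajectory | None = None
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.montage)

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        band_names = {b.name for b in self.bands}
        for condition, effects in self.planted_effects.items():
            if condition not in CONDITIONS:
                raise ValueError(f"unknown condition {condition!r} in planted_effects")
            for channel, band, mult in effects:
                if channel not in self.montage:
                    raise ValueError(
                        f"planted effect names unknown channel {channel!r}"
                    )
                if band not in band_names:
                    raise ValueError(f"planted effect names unknown band {band!r}")
                if mult < 1:
                    raise ValueError(
                        f"power multiplier must be >= 1, got {mult} for "
                        f"({channel}, {band})"
                    )


def _condition_rng(config: SyntheticConfig, condition: str, stream: int = 0) -> np.random.Generator:
    """Independent generator per (seed, condition, stream), reproducible."""
    key = CONDITIONS.index(condition)
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(key, stream))
    return np.random.default_rng(ss)


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, rate: float,
    exponent: float, amplitude: float,
) -> np.ndarray:
    """Gaussian 1/f^alpha background via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC component
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    # normalize by the *expected* std so realized band powers stay
    # decoupled from the (high-variance) low-frequency realization
    weights = np.full_like(shape, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    expected_var = float((weights * shape**2).sum()) / n_samples
    return shaped / np.sqrt(expected_var) * amplitude


def _band_limited_noise(
    rng: np.random.Generator, n_samples: int, rate: float, band: BandDefinition
) -> np.ndarray:
    """Stochastic oscillation confined to one band, unit in-band power."""
    high = min(band.high, 0.499 * rate)
    sos = signal.butter(4, [band.low, high], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n_samples + int(2 * rate)))
    x = x[int(2 * rate):]  # discard filter warm-up
    p = _band_power(x, rate, band)
    return x / np.sqrt(p if p > 0 else 1.0)


def _band_power(x: np.ndarray, rate: float, band: BandDefinition) -> float:
    """Realized power of ``x`` inside one band (Welch integral)."""
    nperseg = min(len(x), int(4 * rate))
    freqs, psd = signal.welch(x, fs=rate, nperseg=nperseg)
    mask = (freqs >= band.low) & (freqs <= band.high)
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _render_session(
    config: SyntheticConfig,
    condition: str,
    intensity: np.ndarray | None,
) -> EEGRecording:
    """Background plus planted oscillations with per-sample intensity gain.

    ``intensity`` is the state trajectory sampled at every time point
    (``None`` means constant 1). The planted component's variance scales
    with intensity so that realized band power interpolates between the
    neutral level (intensity 0) and ``multiplier`` times it (intensity 1).
    """
    n_samples = int(round(config.session_length * config.rate))
    if n_samples < 2:
        raise ValueError("session_length too short")
    rng = _condition_rng(config, condition, stream=0)
    data = _pink_noise(
        rng, config.n_channels, n_samples, config.rate,
        config.noise_exponent, config.amplitude_uv,
    )
    effects = config.planted_effects.get(condition, ())
    if condition == "commercial":
        effects = config.planted_effects.get("commercial", ())
    bands_by_name = {b.name: b for b in config.bands}
    for k, (channel, band_name, mult) in enumerate(effects):
        if mult == 1.0:
            continue
        ch = config.montage.index(channel)
        band = bands_by_name[band_name]
        base_power = _band_power(data[ch], config.rate, band)
        osc_rng = _condition_rng(config, condition, stream=k + 1)
        osc = _band_limited_noise(osc_rng, n_samples, config.rate, band)
        amp = np.sqrt((mult - 1.0) * base_power)
        if intensity is not None:
            amp = amp * np.sqrt(np.clip(intensity, 0.0, 1.0))
        data[ch] = data[ch] + amp * osc
    return EEGRecording(
        subject_id="sim",
        session_label=condition,
        montage=config.montage,
        rate=config.rate,
        data=data,
    )


def generate_session(config: SyntheticConfig, condition: str) -> EEGRecording:
    """Generate one calibration session for a named condition.

    ``neutral`` sessions are pure background; target conditions add the
    configured planted effects at full strength. ``commercial`` delegates
    to :func:`generate_commercial` using ``config.trajectory``.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    if condition == "commercial":
        rec, _ = generate_commercial(config, config.trajectory)
        return rec
    return _render_session(config, condition, intensity=None)


def generate_commercial(
    config: SyntheticConfig,
    trajectory: Trajectory | None = None,
    *,
    condition: str = "happiness",
    clip_id: str = "clip",
    window_s: float = 0.25,
) -> tuple[EEGRecording, np.ndarray]:
    """Generate a commercial-viewing session with a scripted state trajectory.

    The planted effects of ``condition`` are modulated sample-by-sample by
    the trajectory (state intensity in [0, 1] over session time). Returns
    the recording plus the ground-truth mean intensity of every
    non-overlapping ``window_s`` window.
    """
    traj = trajectory if trajectory is not None else config.trajectory
    if traj is None:
        raise ValueError("a trajectory is required for commercial sessions")
    n_samples = int(round(config.session_length * config.rate))
    times = np.arange(n_samples) / config.rate
    intensity = np.asarray(traj(times), dtype=float)
    if intensity.shape != times.shape:
        raise ValueError("trajectory must return one intensity per time point")
    if intensity.min() < -1e-9 or intensity.max() > 1 + 1e-9:
        raise ValueError("trajectory intensities must lie in [0, 1]")
    commercial_cfg = replace(
        config,
        planted_effects={
            **dict(config.planted_effects),
            "commercial": config.planted_effects.get(condition, ()),
        },
    )
    rec = _render_session(commercial_cfg, "commercial", intensity=intensity)
    rec = rec.copy_with(session_label=clip_id)
    spw = int(round(config.rate * window_s))
    n_windows = n_samples // spw
    truth = intensity[: n_windows * spw].reshape(n_windows, spw).mean(axis=1)
    return rec, truth
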