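"""Filtering, re-referencing, and windowing of raw recordings.

The preprocessing chain mirrors standard consumer-EEG practice: a
zero-phase Butterworth band-pass, common average re-referencing to damp
shared artifacts, and segmentation into contiguous non-overlapping
quarter-second windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = ["EpochSet", "bandpass", "common_average_reference", "segment"]

#: Upper band edge is clamped to this fraction of the sampling rate so the
#: requested pass-band stays realizable below Nyquist.
MAX_EDGE_FRACTION = 0.45


@dataclass
class EpochSet:
    """Contiguous non-overlapping windows cut from one recording.

    ``epochs`` has shape (n_windows, n_channels, samples_per_window); the
    windows partition the leading part of the recording and any trailing
    partial window is dropped.
    """

    subject_id: str
    session_label: str
    montage: tuple[str, ...]
    rate: float
    window_s: float
    epochs: np.ndarray = field(repr=False)
    window_start_times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (windows, channels, samples)")
        expected = int(round(self.rate * self.window_s))
        if self.epochs.shape[-1] != expected:
            raise ValueError(
                f"samples per window {self.epochs.shape[-1]} != "
                f"round(rate * window_s) = {expected}"
            )
        if self.epochs.shape[0] != len(self.window_start_times):
            raise ValueError("one start time per window required")

    @property
    def n_windows(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_window(self) -> int:
        return self.epochs.shape[-1]


def bandpass(
    rec: EEGRecording,
    low: float = 0.5,
    high: float = 100.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter.

    Applies a 4th-order Butterworth band-pass forward and backward
    (``sosfiltfilt``), so the pass band has unit gain and no phase
    distortion. If ``high`` is not realizable at the recording's sampling
    rate, it is clamped to ``0.45 * rate`` with a warning — e.g. the
    conventional 0.5-100 Hz EEG band becomes 0.5-57.6 Hz at 128 Hz.
    """
    if high <= low:
        raise ValueError(f"high edge {high} must exceed low edge {low}")
    if not np.isfinite(rec.data).all():
        raise ValueError("recording contains non-finite samples")
    nyq = rec.rate / 2
    max_high = MAX_EDGE_FRACTION * rec.rate
    if high > max_high:
        warnings.warn(
            f"band-pass upper edge {high} Hz not realizable at "
            f"{rec.rate} Hz sampling (Nyquist {nyq} Hz); clamping to "
            f"{max_high:.6g} Hz",
            UserWarning,
            stacklevel=2,
        )
        high = max_high
    if high <= low:
        raise ValueError(
            f"low edge {low} Hz is at or above the clamped upper edge "
            f"{high:.6g} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data=filtered)


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel.

    After re-referencing, the channel mean is zero at every sample.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    referenced = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=referenced)


def segment(rec: EEGRecording, window_s: float = 0.25) -> EpochSet:
    """Cut a recording into contiguous non-overlapping windows.

    The number of windows is ``floor(n_samples / samples_per_window)``; a
    trailing partial window is dropped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    spw = int(round(rec.rate * window_s))
    if rec.n_samples < spw:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{spw}-sample window"
        )
    n_windows = rec.n_samples // spw
    trimmed = rec.data[:, : n_windows * spw]
    epochs = trimmed.reshape(rec.n_channels, n_windows, spw).transpose(1, 0, 2)
    starts = np.arange(n_windows) * window_s
    return EpochSet(
        subject_id=rec.subject_id,
        session_label=rec.session_label,
        montage=rec.montage,
        rate=rec.rate,
        window_s=window_s,
        epochs=epochs.copy(),
        window_start_times=starts,
    )
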