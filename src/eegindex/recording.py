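"""Core container for multichannel EEG recordings.

A recording is a channels-by-samples matrix in microvolts, tagged with the
electrode montage (International 10/20 labels), the sampling rate, and
subject/session identity. The default montage is the 14-channel consumer
headset layout used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: 14-channel 10/20 montage (consumer EEG headset layout), fixed order.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Default sampling rate in Hz.
DEFAULT_RATE: float = 128.0


@dataclass
class EEGRecording:
    """Channels x samples EEG signal with montage and session metadata.

    Parameters
    ----------
    subject_id : str
        Subject label.
    session_label : str
        Condition name (``neutral``, ``happiness``, ...) or a commercial
        clip identifier.
    montage : tuple of str
        Ordered, unique channel labels; row ``i`` of ``data`` is channel
        ``montage[i]``.
    rate : float
        Sampling rate in Hz, strictly positive.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    session_label: str
    montage: tuple[str, ...]
    rate: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage lists "
                f"{len(self.montage)} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.rate

    def channel_index(self, label: str) -> int:
        """Row index of a channel label; raises ``KeyError`` if absent."""
        try:
            return self.montage.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in montage {list(self.montage)}"
            ) from None

    def copy_with(self, **changes) -> "EEGRecording":
        """Return a copy with selected fields replaced."""
        return replace(self, **changes)
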