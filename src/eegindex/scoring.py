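"""Index time series for commercial clips: score, summarize, rank, peaks.

A trained state discriminant applied to a clip's windows yields posterior
probabilities of the target state; these are mapped affinely onto
[-1, 1] via index = 2p - 1, giving one index value per quarter-second
window. Clip-level comparison averages the index within subject, then
across subjects; elapsed-time analysis averages across subjects pointwise
and reports maximal runs of supra-threshold windows as peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import flda
from .features import FeatureMatrix
from .flda import FLDAModel

__all__ = [
    "IndexSeries",
    "ClipSummary",
    "PeakWindow",
    "score_clip",
    "summarize_clips",
    "summary_table",
    "group_average_series",
    "detect_peaks",
]


@dataclass
class IndexSeries:
    """Per-window normalized index in [-1, 1] for one clip and subject."""

    subject_id: str
    index_name: str
    clip_id: str
    window_start_times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    window_s: float = 0.25

    def __post_init__(self) -> None:
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.window_start_times.shape:
            raise ValueError("values and start times must align")
        if self.values.size and (
            self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("index values must lie in [-1, 1]")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def mean(self) -> float:
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_start_s": self.window_start_times, "value": self.values}
        )


@dataclass
class ClipSummary:
    """Group-level summary of one index for one clip."""

    clip_id: str
    index_name: str
    subject_means: dict[str, float]
    mean: float
    sd: float
    rank: int


@dataclass
class PeakWindow:
    """A maximal run of consecutive supra-threshold windows."""

    start_s: float
    end_s: float
    peak: float
    threshold: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def score_clip(
    model: FLDAModel,
    chosen_features: Sequence[str],
    clip: FeatureMatrix,
    index_name: str = "",
) -> IndexSeries:
    """Score every window of a clip with a trained state model.

    ``chosen_features`` are the column names selected for this subject and
    index; the clip's feature matrix must contain all of them. The output
    value at window t is ``2 * posterior(x_t) - 1``.
    """
    names = clip.feature_names
    missing = [f for f in chosen_features if f not in names]
    if missing:
        raise KeyError(f"clip feature matrix is missing columns {missing}")
    cols = [names.index(f) for f in chosen_features]
    X = clip.values[:, cols]
    p = np.asarray(flda.posterior(model, X))
    return IndexSeries(
        subject_id=clip.subject_id,
        index_name=index_name,
        clip_id=clip.session_label,
        window_start_times=clip.window_start_times.copy(),
        values=2.0 * p - 1.0,
    )


def summarize_clips(series: Iterable[IndexSeries]) -> list[ClipSummary]:
    """Per-clip, per-index group summary with ranks.

    The subject-level statistic is the mean index over windows; the group
    statistic is the mean and SD of those subject means. Rank 1 is the
    largest group mean per index; ties break by clip label order.
    """
    series = list(series)
    if not series:
        raise ValueError("no index series to summarize")
    by_key: dict[tuple[str, str], dict[str, float]] = {}
    for s in series:
        if s.n_windows == 0:
            raise ValueError(f"empty series for clip {s.clip_id!r}")
        by_key.setdefault((s.index_name, s.clip_id), {})[s.subject_id] = s.mean()
    summaries: list[ClipSummary] = []
    index_names = sorted({k[0] for k in by_key})
    for index_name in index_names:
        clips = sorted(k[1] for k in by_key if k[0] == index_name)
        stats = []
        for clip in clips:
            means = by_key[(index_name, clip)]
            vals = np.array(list(means.values()))
            stats.append(
                (clip, means, float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
            )
        # rank 1 = largest mean; ties resolved by clip label order
        order = sorted(range(len(stats)), key=lambda i: (-stats[i][2], stats[i][0]))
        ranks = {stats[i][0]: r + 1 for r, i in enumerate(order)}
        for clip, means, mean, sd in stats:
            summaries.append(
                ClipSummary(
                    clip_id=clip,
                    index_name=index_name,
                    subject_means=means,
                    mean=mean,
                    sd=sd,
                    rank=ranks[clip],
                )
            )
    return summaries


def summary_table(summaries: Iterable[ClipSummary]) -> pd.DataFrame:
    """Flat table of clip summaries (one row per clip per index)."""
    rows = [
        {
            "index_name": s.index_name,
            "clip_id": s.clip_id,
            "n_subjects": len(s.subject_means),
            "mean": s.mean,
            "sd": s.sd,
            "rank": s.rank,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def group_average_series(series: Iterable[IndexSeries]) -> IndexSeries:
    """Pointwise mean across subjects for one clip and index.

    Subjects are truncated to the shortest window grid before averaging.
    """
    series = list(series)
    if not series:
        raise ValueError("no subjects to average")
    clip_ids = {s.clip_id for s in series}
    index_names = {s.index_name for s in series}
    if len(clip_ids) > 1 or len(index_names) > 1:
        raise ValueError(
            f"cannot average across clips {clip_ids} / indices {index_names}"
        )
    n = min(s.n_windows for s in series)
    values = np.mean([s.values[:n] for s in series], axis=0)
    return IndexSeries(
        subject_id="group",
        index_name=series[0].index_name,
        clip_id=series[0].clip_id,
        window_start_times=series[0].window_start_times[:n].copy(),
        values=values,
        window_s=series[0].window_s,
    )


def detect_peaks(avg: IndexSeries, threshold: float = 0.5) -> list[PeakWindow]:
    """Maximal runs of consecutive windows with index above a threshold.

    Adjacent supra-threshold windows merge into one peak; an isolated
    window is a valid quarter-second peak. Returns an empty list when no
    window exceeds the threshold.
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (-1, 1)")
    above = avg.values > threshold
    peaks: list[PeakWindow] = []
    i = 0
    n = avg.n_windows
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        peaks.append(
            PeakWindow(
                start_s=float(avg.window_start_times[i]),
                end_s=float(avg.window_start_times[j] + avg.window_s),
                peak=float(avg.values[i : j + 1].max()),
                threshold=threshold,
            )
        )
        i = j + 1
    return peaks
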