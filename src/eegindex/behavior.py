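"""Behavioral scoring and group comparison of per-clip measures.

Subjects rank the clips on preference, short-term memory, and recall;
ranks are converted to points (first of four ranks -> 4 points, last -> 1)
so larger is better, and purchase intention is a 1-7 Likert rating. Clip
comparisons use a one-way ANOVA omnibus test followed by all pairwise
paired t-tests with Holm adjustment (the design is within-subject); a
rank-based alternative (Friedman omnibus + Wilcoxon pairwise) is available
via ``method="friedman"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "rank_to_points", "behavioral_summary", "compare_groups"]


@dataclass
class GroupComparison:
    """Omnibus statistic plus Holm-adjusted pairwise comparisons."""

    method: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame = field(repr=False)

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.pairwise[self.pairwise["p_adj"] < alpha]


def rank_to_points(rank, n_clips: int = 4):
    """Convert a preference rank (1 = best) to points: first of four -> 4.

    Points are ``n_clips + 1 - rank``; accepts scalars or arrays and
    rejects out-of-range ranks.
    """
    r = np.asarray(rank)
    if np.any((r < 1) | (r > n_clips)):
        raise ValueError(f"ranks must lie in 1..{n_clips}")
    points = n_clips + 1 - r
    return points if points.ndim else points.item()


def behavioral_summary(records: pd.DataFrame, n_clips: int | None = None) -> pd.DataFrame:
    """Per-clip mean +/- SD of the point-converted behavioral measures.

    ``records`` has one row per (subject, clip) with columns
    ``subject_id, clip_id, preference_rank, stm_rank, recall_rank,
    purchase_intention``. Rank columns are converted to points; the Likert
    purchase-intention column is summarized as-is.
    """
    required = {"subject_id", "clip_id"}
    if not required <= set(records.columns):
        raise ValueError(f"records must contain columns {sorted(required)}")
    if n_clips is None:
        n_clips = records["clip_id"].nunique()
    out = records.copy()
    for col in ("preference_rank", "stm_rank", "recall_rank"):
        if col in out.columns:
            out[col.replace("_rank", "_points")] = rank_to_points(
                out[col].to_numpy(), n_clips
            )
    value_cols = [
        c for c in ("preference_points", "stm_points", "recall_points", "purchase_intention")
        if c in out.columns
    ]
    grouped = out.groupby("clip_id")[value_cols]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{c}_{stat}" for c, stat in summary.columns]
    return summary.reset_index()


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 1.0  # identical data: no evidence of a difference
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 1.0
    w, p = stats.wilcoxon(a, b, zero_method="wilcox")
    return float(w), float(p)


def compare_groups(
    values: pd.DataFrame | np.ndarray,
    *,
    method: str = "anova",
) -> GroupComparison:
    """Compare per-subject clip scores across clips.

    Parameters
    ----------
    values : DataFrame or ndarray, shape (n_subjects, n_clips)
        One score per subject per clip (columns = clips). A DataFrame's
        column labels name the clips.
    method : {"anova", "friedman"}
        ``anova``: one-way ANOVA omnibus + paired t-tests. ``friedman``:
        Friedman omnibus + Wilcoxon signed-rank pairwise. Pairwise p-values
        are Holm-adjusted in both cases; significance is flagged at
        alpha = 0.05 and 0.01.
    """
    if isinstance(values, pd.DataFrame):
        clip_labels = [str(c) for c in values.columns]
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        clip_labels = [f"C{j + 1}" for j in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a subjects x clips matrix with >= 2 clips")
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 subjects")

    columns = [arr[:, j] for j in range(arr.shape[1])]
    if method == "anova":
        if all(np.allclose(c, c[0]) for c in columns) and all(
            np.allclose(c, columns[0]) for c in columns
        ):
            omnibus_stat, omnibus_p = 0.0, 1.0
        else:
            omnibus_stat, omnibus_p = stats.f_oneway(*columns)
        pair_test = _paired_t
        stat_name = "t"
    elif method == "friedman":
        omnibus_stat, omnibus_p = stats.friedmanchisquare(*columns)
        pair_test = _paired_wilcoxon
        stat_name = "W"
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for i, j in combinations(range(arr.shape[1]), 2):
        s, p = pair_test(columns[i], columns[j])
        rows.append(
            {
                "clip_a": clip_labels[i],
                "clip_b": clip_labels[j],
                stat_name: s,
                "p_raw": p,
            }
        )
    pairwise = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(pairwise["p_raw"].to_numpy(), method="holm")
    pairwise["p_adj"] = p_adj
    pairwise["sig_05"] = pairwise["p_adj"] < 0.05
    pairwise["sig_01"] = pairwise["p_adj"] < 0.01
    return GroupComparison(
        method=method,
        omnibus_stat=float(omnibus_stat),
        omnibus_p=float(omnibus_p),
        pairwise=pairwise,
    )
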