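"""ANOVA-seeded greedy forward feature selection with k-fold CV.

For each subject and each target state, windows from the neutral session
and the target-condition session are pooled and labeled. Every feature is
first scored with a one-way ANOVA F statistic (for two classes, F = t^2);
the top-F feature seeds the subset. The search then repeatedly adds the
candidate that maximizes stratified tenfold cross-validated accuracy of a
Fisher discriminant on the augmented subset, and stops when the best
achievable accuracy falls below the current one. Equal-accuracy plateaus
are explored but retained only up to the last strict improvement, so the
returned trajectory is non-decreasing and the set stays compact.

Accuracies are exact rationals with a common denominator (the pooled
window count), so they are compared exactly, with ties broken by higher
F value and then by lower feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import flda
from .features import FeatureMatrix

__all__ = [
    "LabeledFeatures",
    "SelectionResult",
    "anova_f",
    "cross_validate",
    "greedy_forward_select",
]


@dataclass
class LabeledFeatures:
    """Pooled windows from a neutral and a target-condition session.

    ``y`` is 0 for neutral windows and 1 for target windows.
    """

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y).astype(int).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("label length must equal row count")
        if not self.feature_names:
            self.feature_names = tuple(f"f{j}" for j in range(self.X.shape[1]))
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature column required")
        for c in (0, 1):
            if (self.y == c).sum() == 0:
                raise ValueError(f"class {c} is empty")

    @classmethod
    def from_sessions(
        cls, neutral: FeatureMatrix, target: FeatureMatrix
    ) -> "LabeledFeatures":
        """Pool a neutral and a target feature matrix (labels 0/1)."""
        if neutral.feature_index != target.feature_index:
            raise ValueError("sessions have different feature layouts")
        X = np.vstack([neutral.values, target.values])
        y = np.concatenate(
            [np.zeros(neutral.n_windows, int), np.ones(target.n_windows, int)]
        )
        return cls(X=X, y=y, feature_names=tuple(neutral.feature_names))


@dataclass
class SelectionResult:
    """Ordered chosen features with the CV-accuracy trajectory."""

    subject_id: str
    index_name: str
    chosen: tuple[int, ...]
    chosen_names: tuple[str, ...]
    f_values: np.ndarray = field(repr=False)
    cv_trajectory: tuple[float, ...] = ()
    final_cv_accuracy: float = 0.0
    folds: int = 10
    seed: int = 0

    @property
    def n_chosen(self) -> int:
        return len(self.chosen)

    def to_table(self) -> pd.DataFrame:
        """One row per chosen feature: rank, channel, band, F, CV accuracy."""
        rows = []
        for rank, (j, name, acc) in enumerate(
            zip(self.chosen, self.chosen_names, self.cv_trajectory), start=1
        ):
            channel, _, band = name.partition("_")
            rows.append(
                {
                    "rank": rank,
                    "channel": channel,
                    "band": band,
                    "F": float(self.f_values[j]),
                    "cv_accuracy": float(acc),
                }
            )
        return pd.DataFrame(rows)


def anova_f(data: LabeledFeatures) -> np.ndarray:
    """One-way ANOVA F statistic per feature (two groups: F = t^2).

    Zero within-group variance with separated means yields ``+inf`` with a
    warning; a fully constant feature yields 0.
    """
    X, y = data.X, data.y
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} needs >= 2 windows for the ANOVA")
    n = X.shape[0]
    k = 2
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c in (0, 1):
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        ssb += Xc.shape[0] * (mu - grand) ** 2
        ssw += ((Xc - mu) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    degenerate = ssw == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) have zero within-group "
            "variance; F set to +inf where class means differ",
            UserWarning,
            stacklevel=2,
        )
        F[degenerate & (ssb > 0)] = np.inf
        F[degenerate & (ssb == 0)] = 0.0
    return F


def _folds(data: LabeledFeatures, folds: int, seed: int):
    counts = [int((data.y == c).sum()) for c in (0, 1)]
    if min(counts) < folds:
        raise ValueError(
            f"smallest class has {min(counts)} windows, fewer than "
            f"{folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(data.X, data.y))


def _cv_accuracy(data: LabeledFeatures, subset, splits) -> float:
    subset = list(subset)
    X = data.X[:, subset]
    y = data.y
    correct = 0
    for train_idx, test_idx in splits:
        model = flda.fit(X[train_idx], y[train_idx])
        pred = flda.classify(model, X[test_idx])
        correct += int((pred == y[test_idx]).sum())
    return correct / len(y)


def cross_validate(
    data: LabeledFeatures, subset, folds: int = 10, seed: int = 0
) -> float:
    """Stratified k-fold CV accuracy of the discriminant on a feature subset.

    Fold assignment is fixed by ``seed``; accuracy is pooled
    correct / total over all held-out folds.
    """
    return _cv_accuracy(data, subset, _folds(data, folds, seed))


def greedy_forward_select(
    data: LabeledFeatures,
    folds: int = 10,
    seed: int = 0,
    *,
    subject_id: str = "",
    index_name: str = "",
    max_features: int | None = None,
    plateau: str = "stop",
) -> SelectionResult:
    """Greedy forward selection seeded by the top-F feature.

    The fold assignment is fixed once per call, so candidate accuracies are
    comparable exactly. The search adds the accuracy-maximizing candidate
    (ties: higher F, then lower column index) and stops when the best
    achievable accuracy no longer strictly improves on the current one
    (``plateau="stop"``, the default). With ``plateau="explore"``
    equal-accuracy additions keep the search alive but are retained only
    if a later strict improvement occurs; this variant admits more
    chance-level additions on noisy data, so the stricter rule is the
    default.
    """
    if plateau not in ("stop", "explore"):
        raise ValueError(f"plateau must be 'stop' or 'explore', got {plateau!r}")
    F = anova_f(data)
    splits = _folds(data, folds, seed)
    n_features = data.X.shape[1]
    cap = n_features if max_features is None else min(max_features, n_features)

    # seed feature: max F, ties to the lower index (np.argmax convention)
    first = int(np.argmax(F))
    chosen = [first]
    acc = _cv_accuracy(data, chosen, splits)
    trajectory = [acc]
    last_strict = 1  # prefix length ending at the last strict improvement

    remaining = [j for j in range(n_features) if j != first]
    while remaining and len(chosen) < cap:
        best_j, best_acc = None, -1.0
        for j in remaining:
            a = _cv_accuracy(data, chosen + [j], splits)
            if a > best_acc or (
                a == best_acc
                and best_j is not None
                and (F[j], -j) > (F[best_j], -best_j)
            ):
                best_j, best_acc = j, a
        if best_acc < acc or (plateau == "stop" and best_acc == acc):
            break
        chosen.append(best_j)
        trajectory.append(best_acc)
        remaining.remove(best_j)
        if best_acc > acc:
            last_strict = len(chosen)
        acc = best_acc

    chosen = chosen[:last_strict]
    trajectory = trajectory[:last_strict]
    return SelectionResult(
        subject_id=subject_id,
        index_name=index_name,
        chosen=tuple(chosen),
        chosen_names=tuple(data.feature_names[j] for j in chosen),
        f_values=F,
        cv_trajectory=tuple(trajectory),
        final_cv_accuracy=trajectory[-1],
        folds=folds,
        seed=seed,
    )
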