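"""ANOVA seeding, cross-validation, and greedy forward selection."""

import numpy as np
import pytest
from scipy import stats

from eegindex import (
    LabeledFeatures,
    anova_f,
    cross_validate,
    greedy_forward_select,
)


def null_data(rng, n_per_class=100, d=10):
    X = rng.standard_normal((2 * n_per_class, d))
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return LabeledFeatures(X=X, y=y)


def test_f_equals_squared_t_for_two_groups():
    rng = np.random.default_rng(0)
    data = null_data(rng, 40, 5)
    F = anova_f(data)
    for j in range(5):
        t, _ = stats.ttest_ind(
            data.X[data.y == 0, j], data.X[data.y == 1, j], equal_var=True
        )
        assert abs(F[j] - t**2) < 1e-8


def test_null_f_has_mean_near_one():
    rng = np.random.default_rng(1)
    data = null_data(rng, 500, 200)
    F = anova_f(data)
    assert np.all(F >= 0)
    assert abs(F.mean() - 1.0) < 0.2


def test_shifted_feature_dominates_f():
    rng = np.random.default_rng(2)
    data = null_data(rng, 100, 8)
    data.X[data.y == 1, 3] += 5.0
    assert int(np.argmax(anova_f(data))) == 3


def test_zero_variance_feature_warns_inf():
    rng = np.random.default_rng(3)
    data = null_data(rng, 20, 3)
    data.X[:, 1] = data.y  # constant within each class, means differ
    with pytest.warns(UserWarning, match="zero within-group"):
        F = anova_f(data)
    assert np.isinf(F[1])


def test_anova_needs_two_windows_per_class():
    X = np.zeros((3, 2))
    with pytest.raises(ValueError):
        anova_f(LabeledFeatures(X=X, y=np.array([0, 0, 1])))


def test_perfectly_separated_feature_gives_accuracy_one():
    rng = np.random.default_rng(4)
    data = null_data(rng, 50, 3)
    data.X[data.y == 1, 0] += 10.0
    assert cross_validate(data, [0], seed=0) == 1.0


def test_null_cv_accuracy_stays_near_chance():
    """Permuted labels, n = 200/class: accuracy in [0.40, 0.60] across
    20 seeds."""
    rng = np.random.default_rng(5)
    for seed in range(20):
        data = null_data(np.random.default_rng(100 + seed), 200, 5)
        acc = cross_validate(data, [0, 1, 2], seed=seed)
        assert 0.40 <= acc <= 0.60


def test_cv_deterministic_in_seed():
    rng = np.random.default_rng(6)
    data = null_data(rng, 50, 4)
    a = cross_validate(data, [0, 1], folds=10, seed=3)
    b = cross_validate(data, [0, 1], folds=10, seed=3)
    c = cross_validate(data, [0, 1], folds=10, seed=4)
    assert a == b
    assert isinstance(c, float)


def test_cv_requires_class_at_least_folds():
    rng = np.random.default_rng(7)
    data = null_data(rng, 5, 2)
    with pytest.raises(ValueError, match="fold"):
        cross_validate(data, [0], folds=10)


def test_single_informative_feature_recovered():
    """One 3 SD feature among noise: it seeds the selection in >= 18/20
    seeds (planted-recovery simulation)."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        data = null_data(rng, 200, 12)
        data.X[data.y == 1, 7] += 3.0
        res = greedy_forward_select(data, seed=seed)
        hits += res.chosen[0] == 7
    assert hits >= 18


def test_greedy_result_invariants(planted_labeled):
    res = greedy_forward_select(planted_labeled, seed=11, subject_id="s", index_name="happiness")
    # chosen seeded by max F, duplicate-free subset of candidates
    assert res.chosen[0] == int(np.argmax(res.f_values))
    assert len(set(res.chosen)) == len(res.chosen)
    assert set(res.chosen) <= set(range(planted_labeled.X.shape[1]))
    # retained trajectory strictly improves, so it is non-decreasing
    traj = np.array(res.cv_trajectory)
    assert np.all(np.diff(traj) > 0)
    assert res.final_cv_accuracy == traj[-1]
    # plausible chosen-set size on real-structure synthetic data
    assert 2 <= res.n_chosen <= 20


def test_greedy_planted_eeg_features_rank_first(planted_labeled):
    """On planted EEG features, the top chosen cells are the planted
    happiness sites."""
    res = greedy_forward_select(planted_labeled, seed=1)
    assert set(res.chosen_names[:2]) & {"FC5_high_beta", "T8_gamma"}
    assert res.final_cv_accuracy > 0.7


def test_greedy_deterministic(planted_labeled):
    r1 = greedy_forward_select(planted_labeled, seed=5)
    r2 = greedy_forward_select(planted_labeled, seed=5)
    assert r1.chosen == r2.chosen
    assert r1.cv_trajectory == r2.cv_trajectory


def test_rejected_candidate_would_not_improve(planted_labeled):
    """Appending any unchosen candidate to the final set does not raise
    the fixed-fold CV accuracy (the stopping condition)."""
    res = greedy_forward_select(planted_labeled, seed=2)
    best_rejected = -1.0
    rng = np.random.default_rng(0)
    candidates = [j for j in range(planted_labeled.X.shape[1]) if j not in res.chosen]
    for j in rng.choice(candidates, size=10, replace=False):
        acc = cross_validate(
            planted_labeled, list(res.chosen) + [int(j)], seed=res.seed
        )
        best_rejected = max(best_rejected, acc)
    assert best_rejected <= res.final_cv_accuracy


def test_plateau_explore_variant_runs(planted_labeled):
    res = greedy_forward_select(planted_labeled, seed=2, plateau="explore")
    traj = np.array(res.cv_trajectory)
    assert np.all(np.diff(traj) >= 0)
    with pytest.raises(ValueError, match="plateau"):
        greedy_forward_select(planted_labeled, plateau="maybe")


def test_selection_table_layout(planted_labeled):
    res = greedy_forward_select(
        planted_labeled, seed=3, subject_id="sub-01", index_name="happiness"
    )
    table = res.to_table()
    assert list(table.columns) == ["rank", "channel", "band", "F", "cv_accuracy"]
    assert len(table) == res.n_chosen
    assert table["rank"].tolist() == list(range(1, res.n_chosen + 1))
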