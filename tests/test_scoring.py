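"""Index series construction, summaries, group averages, and peaks."""

import numpy as np
import pytest

from eegindex import flda
from eegindex.features import FeatureMatrix
from eegindex.scoring import (
    IndexSeries,
    detect_peaks,
    group_average_series,
    score_clip,
    summarize_clips,
    summary_table,
)


def one_feature_matrix(values, subject="s1", clip="C1"):
    values = np.asarray(values, dtype=float)[:, None]
    return FeatureMatrix(
        feature_index=(("O1", "alpha"),),
        values=values,
        window_start_times=np.arange(len(values)) * 0.25,
        subject_id=subject,
        session_label=clip,
    )


def unit_model():
    """d = 1 discriminant, classes at -1 / +1, unit variances."""
    return flda.FLDAModel(
        w=np.array([1.0]),
        class_means=np.array([[-1.0], [1.0]]),
        grand_mean=np.array([0.0]),
        S_B=np.eye(1),
        S_W=np.eye(1),
        proj_means=np.array([-1.0, 1.0]),
        proj_vars=np.array([1.0, 1.0]),
    )


def series(values, subject="s1", clip="C1", index="happiness"):
    values = np.asarray(values, dtype=float)
    return IndexSeries(
        subject_id=subject,
        index_name=index,
        clip_id=clip,
        window_start_times=np.arange(len(values)) * 0.25,
        values=values,
    )


def test_midpoint_posterior_maps_to_zero_index():
    fm = one_feature_matrix([0.0, 0.0, 0.0])
    out = score_clip(unit_model(), ["O1_alpha"], fm, index_name="happiness")
    assert np.allclose(out.values, 0.0)


def test_extreme_posteriors_hit_index_endpoints():
    fm = one_feature_matrix([60.0, -60.0])
    out = score_clip(unit_model(), ["O1_alpha"], fm)
    assert out.values[0] == pytest.approx(1.0)
    assert out.values[1] == pytest.approx(-1.0)


def test_index_strictly_increasing_in_projection():
    z = np.linspace(-4, 4, 41)
    out = score_clip(unit_model(), ["O1_alpha"], one_feature_matrix(z))
    assert np.all(np.diff(out.values) > 0)
    assert np.all(np.abs(out.values) <= 1)


def test_missing_feature_column_named():
    fm = one_feature_matrix([0.0, 1.0])
    with pytest.raises(KeyError, match="T8_gamma"):
        score_clip(unit_model(), ["T8_gamma"], fm)


def test_identical_series_rank_by_label_order():
    ss = [series([0.2, 0.2], clip=c) for c in ("C2", "C1", "C3")]
    summaries = summarize_clips(ss)
    assert [s.mean for s in summaries] == pytest.approx([0.2] * 3)
    ranks = {s.clip_id: s.rank for s in summaries}
    assert ranks == {"C1": 1, "C2": 2, "C3": 3}


def test_single_subject_constant_summary():
    summaries = summarize_clips([series([0.4, 0.4, 0.4])])
    (s,) = summaries
    assert s.mean == pytest.approx(0.4)
    assert s.sd == 0.0
    assert s.rank == 1


def test_summary_table_shape():
    ss = [series([0.1], clip=c, subject=sub)
          for c in ("C1", "C2") for sub in ("a", "b")]
    tab = summary_table(summarize_clips(ss))
    assert len(tab) == 2
    assert set(tab.columns) == {
        "index_name", "clip_id", "n_subjects", "mean", "sd", "rank"
    }
    assert tab["n_subjects"].tolist() == [2, 2]


def test_group_average_single_subject_identity():
    s = series([0.1, -0.2, 0.3])
    g = group_average_series([s])
    assert np.allclose(g.values, s.values)
    assert g.subject_id == "group"


def test_group_average_symmetric_cancellation():
    a = series([0.5, -0.3, 0.2], subject="a")
    b = series([-0.5, 0.3, -0.2], subject="b")
    g = group_average_series([a, b])
    assert np.allclose(g.values, 0.0)


def test_group_average_matches_direct_mean():
    rng = np.random.default_rng(0)
    vals = rng.uniform(-1, 1, size=(5, 40))
    ss = [series(v, subject=f"s{i}") for i, v in enumerate(vals)]
    g = group_average_series(ss)
    assert np.abs(g.values - vals.mean(axis=0)).max() < 1e-12


def test_group_average_truncates_to_shortest():
    a = series(np.zeros(10), subject="a")
    b = series(np.zeros(6), subject="b")
    assert group_average_series([a, b]).n_windows == 6


def test_group_average_rejects_mixed_clips():
    with pytest.raises(ValueError, match="cannot average"):
        group_average_series([series([0.0]), series([0.0], clip="C2")])


def test_no_peaks_when_below_threshold():
    assert detect_peaks(series([0.1, 0.5, 0.4]), 0.5) == []


def test_four_isolated_peaks_have_quarter_second_width():
    vals = np.full(80, 0.1)
    for i in (11, 38, 54, 63):  # e.g. a peak spanning 2.75-3.0 s
        vals[i] = 0.8
    peaks = detect_peaks(series(vals), 0.5)
    assert len(peaks) == 4
    assert all(p.duration_s == pytest.approx(0.25) for p in peaks)
    assert peaks[0].start_s == pytest.approx(2.75)
    assert peaks[0].end_s == pytest.approx(3.0)


def test_adjacent_peaks_merge():
    vals = np.full(20, 0.0)
    vals[4:6] = 0.9
    peaks = detect_peaks(series(vals), 0.5)
    assert len(peaks) == 1
    assert peaks[0].duration_s == pytest.approx(0.5)
    assert peaks[0].peak == pytest.approx(0.9)


def test_threshold_validation():
    with pytest.raises(ValueError, match="threshold"):
        detect_peaks(series([0.0]), 1.0)


def test_index_values_bounded_validation():
    with pytest.raises(ValueError, match=r"\[-1, 1\]"):
        series([1.5])


def test_step_trajectory_raises_second_half_index(default_config):
    """End-to-end: a clip whose planted effect steps on at mid-session
    scores higher in its second half (5 seeds)."""
    import warnings

    from eegindex import SyntheticConfig, generate_commercial, piecewise_linear
    from eegindex.pipeline import preprocess_and_features, train_index_model
    from eegindex.simulate import DEFAULT_PLANTED_EFFECTS
    from eegindex import generate_session

    wins = 0
    for seed in range(5):
        cfg = SyntheticConfig(session_length=40.0, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            f_n = preprocess_and_features(
                generate_session(cfg, "neutral"), default_config
            )
            f_h = preprocess_and_features(
                generate_session(cfg, "happiness"), default_config
            )
            result, model = train_index_model(
                f_n, f_h, default_config,
                subject_id=f"s{seed}", index_name="happiness",
            )
            clip_cfg = SyntheticConfig(session_length=20.0, seed=seed + 500)
            step = piecewise_linear([(0, 0), (9.99, 0), (10.01, 1), (20, 1)])
            rec, _ = generate_commercial(clip_cfg, step, condition="happiness")
            fm = preprocess_and_features(rec, default_config)
        out = score_clip(model, result.chosen_names, fm)
        half = out.n_windows // 2
        wins += out.values[half:].mean() > out.values[:half].mean()
    assert wins >= 4
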