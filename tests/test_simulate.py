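"""Generator checks: determinism, effect calibration, trajectories."""

import numpy as np
import pytest
from scipy import signal, stats

from eegindex import (
    SyntheticConfig,
    generate_commercial,
    generate_session,
    piecewise_linear,
)
from eegindex.features import DEFAULT_BANDS

BANDS = {b.name: b for b in DEFAULT_BANDS}


def band_power(x, rate, band):
    """Independent band-power oracle: Welch periodogram band integral."""
    f, p = signal.welch(x, fs=rate, nperseg=min(len(x), 512))
    m = (f >= band.low) & (f <= band.high)
    return np.trapezoid(p[m], f[m])


def window_band_powers(x, rate, band, window_s=0.25):
    spw = int(rate * window_s)
    n = len(x) // spw
    wins = x[: n * spw].reshape(n, spw)
    f, p = signal.periodogram(wins, fs=rate, nfft=256, axis=-1)
    m = (f >= band.low) & (f <= band.high)
    return p[:, m].mean(axis=-1)


def test_same_seed_is_bit_identical():
    cfg = SyntheticConfig(session_length=5.0, seed=9)
    a = generate_session(cfg, "happiness")
    b = generate_session(SyntheticConfig(session_length=5.0, seed=9), "happiness")
    assert np.array_equal(a.data, b.data)
    assert a.montage == b.montage and a.rate == b.rate


def test_different_conditions_differ():
    cfg = SyntheticConfig(session_length=5.0, seed=9)
    a = generate_session(cfg, "neutral")
    b = generate_session(cfg, "surprise")
    assert not np.array_equal(a.data, b.data)


def test_unknown_condition_and_bad_effects_rejected():
    cfg = SyntheticConfig(session_length=5.0)
    with pytest.raises(ValueError, match="unknown condition"):
        generate_session(cfg, "boredom")
    with pytest.raises(ValueError, match="unknown channel"):
        SyntheticConfig(planted_effects={"happiness": (("XX", "alpha", 2.0),)})
    with pytest.raises(ValueError, match="unknown band"):
        SyntheticConfig(planted_effects={"happiness": (("O1", "mu", 2.0),)})
    with pytest.raises(ValueError, match="multiplier"):
        SyntheticConfig(planted_effects={"happiness": (("O1", "alpha", 0.5),)})


def test_unit_multiplier_statistically_matches_neutral():
    """Multiplier 1.0 plants nothing: per-window band powers from the
    condition session and the neutral session are exchangeable."""
    cfg = SyntheticConfig(
        session_length=25.0,
        seed=5,
        planted_effects={"happiness": (("O1", "alpha", 1.0),)},
    )
    neu = generate_session(cfg, "neutral")
    hap = generate_session(cfg, "happiness")
    i = neu.montage.index("O1")
    p_neu = window_band_powers(neu.data[i], 128.0, BANDS["alpha"])
    p_hap = window_band_powers(hap.data[i], 128.0, BANDS["alpha"])
    assert len(p_neu) == 100
    _, p = stats.mannwhitneyu(p_neu, p_hap)
    assert p > 0.01


def test_planted_alpha_power_ratio_matches_multiplier():
    """A 3x alpha plant at O1 realizes a mean 60 s power ratio in [2.5, 3.5]
    over 20 seeds (Welch band-integral oracle)."""
    ratios = []
    for seed in range(20):
        cfg = SyntheticConfig(
            session_length=60.0,
            seed=seed,
            planted_effects={"happiness": (("O1", "alpha", 3.0),)},
        )
        neu = generate_session(cfg, "neutral")
        hap = generate_session(cfg, "happiness")
        i = neu.montage.index("O1")
        ratios.append(
            band_power(hap.data[i], 128.0, BANDS["alpha"])
            / band_power(neu.data[i], 128.0, BANDS["alpha"])
        )
    assert 2.5 <= np.mean(ratios) <= 3.5


def test_unplanted_cells_unaffected():
    ratios = []
    for seed in range(10):
        cfg = SyntheticConfig(
            session_length=60.0,
            seed=seed,
            planted_effects={"happiness": (("O1", "alpha", 3.0),)},
        )
        neu = generate_session(cfg, "neutral")
        hap = generate_session(cfg, "happiness")
        i = neu.montage.index("T7")
        ratios.append(
            band_power(hap.data[i], 128.0, BANDS["theta"])
            / band_power(neu.data[i], 128.0, BANDS["theta"])
        )
    assert abs(np.mean(ratios) - 1.0) < 0.2


def test_commercial_zero_trajectory_is_background_only():
    cfg = SyntheticConfig(session_length=10.0, seed=3)
    flat = piecewise_linear([(0.0, 0.0), (10.0, 0.0)])
    rec, truth = generate_commercial(cfg, flat)
    assert np.allclose(truth, 0.0)
    # no planted power: the happiness channels carry background levels only
    i = rec.montage.index("FC5")
    neu = generate_session(
        SyntheticConfig(session_length=10.0, seed=31, planted_effects={}),
        "neutral",
    )
    r = band_power(rec.data[i], 128.0, BANDS["high_beta"]) / band_power(
        neu.data[i], 128.0, BANDS["high_beta"]
    )
    assert 0.5 < r < 1.5


def test_commercial_step_trajectory_creates_power_change_point():
    """A 0 -> 1 step at mid-session doubles-plus the planted band power in
    the second half (brute-force windowed power oracle)."""
    second_over_first = []
    for seed in range(5):
        cfg = SyntheticConfig(
            session_length=30.0,
            seed=seed,
            planted_effects={"happiness": (("O1", "alpha", 3.0),)},
        )
        step = piecewise_linear([(0.0, 0.0), (14.99, 0.0), (15.01, 1.0), (30.0, 1.0)])
        rec, truth = generate_commercial(cfg, step)
        i = rec.montage.index("O1")
        powers = window_band_powers(rec.data[i], 128.0, BANDS["alpha"])
        half = len(powers) // 2
        second_over_first.append(powers[half:].mean() / powers[:half].mean())
    assert np.mean(second_over_first) > 1.8


def test_ground_truth_has_one_value_per_quarter_second():
    cfg = SyntheticConfig(session_length=30.0, seed=1)
    traj = piecewise_linear([(0.0, 0.0), (30.0, 1.0)])
    _, truth = generate_commercial(cfg, traj)
    assert len(truth) == 120
    assert truth.min() >= 0.0 and truth.max() <= 1.0


def test_trajectory_must_cover_session():
    cfg = SyntheticConfig(session_length=30.0, seed=1)
    short = piecewise_linear([(0.0, 0.0), (10.0, 1.0)])
    with pytest.raises(ValueError, match="trajectory"):
        generate_commercial(cfg, short)


def test_trajectory_intensities_bounded():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        piecewise_linear([(0.0, 0.0), (10.0, 1.5)])
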