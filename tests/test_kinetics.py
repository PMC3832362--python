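"""Video event detection, kinetic endpoints and survival-style tests."""

import itertools

import numpy as np
import pytest

from conftest import timelines
from sicklekit.kinetics import (
    cumulative_curve,
    detect_events,
    gehan_breslow_wilcoxon,
    kinetics_summary,
    sample_frames,
    wilcoxon_times,
)
from sicklekit.simulate.video import (
    FieldLayout,
    KineticsConfig,
    render_video,
    simulate_sickling_times,
)

# ------------------------------------------------------------- frame sampling


def test_thirty_minutes_at_4fps_gives_29_sampled_frames():
    idx = sample_frames(7200, 256)
    assert len(idx) == 29
    assert idx[0] == 0 and idx[-1] == 7168


def test_interval_one_samples_every_frame():
    assert np.array_equal(sample_frames(100, 1), np.arange(100))


def test_oversized_interval_rejected():
    with pytest.raises(ValueError):
        sample_frames(100, 100)


# ------------------------------------------------------------ event detection


def test_transition_at_8p4_min_detected_at_next_sampled_frame():
    cfg = KineticsConfig(n_cells=4, susceptible_fraction=1.0, seed=5)
    truth = simulate_sickling_times(cfg)
    truth["true_time_min"] = [8.4, 40.0, 40.0, 40.0]
    truth["censored"] = [False, True, True, True]
    video = render_video(truth, cfg, FieldLayout())
    tl = detect_events(video)
    assert tl.loc[0, "time_min"] == pytest.approx(8.5333, abs=1e-3)
    assert tl.loc[1:, "censored"].all()


def test_detected_times_on_grid_and_never_before_truth():
    cfg = KineticsConfig(n_cells=80, susceptible_fraction=0.7, seed=9)
    truth = simulate_sickling_times(cfg)
    video = render_video(truth, cfg, FieldLayout())
    tl = detect_events(video)
    det = tl[~tl["censored"]]
    grid = 256 / cfg.fps / 60.0
    multiples = det["time_min"].to_numpy() / grid
    assert np.allclose(multiples, np.round(multiples), atol=1e-9)
    matched = truth.loc[det.index, "true_time_min"]
    assert (det["time_min"].to_numpy() >= matched.to_numpy()).all()


def test_noise_alone_rarely_triggers_detection():
    cfg = KineticsConfig(n_cells=500, susceptible_fraction=0.0, seed=10)
    truth = simulate_sickling_times(cfg)
    tl = detect_events(render_video(truth, cfg, FieldLayout()))
    assert (~tl["censored"]).mean() < 0.02


# ------------------------------------------------------------------ summaries


def test_cumulative_curve_steps_and_final_value():
    curve = cumulative_curve(timelines([5, 6, 7, np.inf, np.inf, np.inf]))
    assert curve["sickled_fraction"].iloc[0] == 0.0
    assert curve["sickled_fraction"].tolist()[1:4] == [1 / 6, 2 / 6, 3 / 6]
    assert curve["sickled_fraction"].iloc[-1] == 0.5
    assert (np.diff(curve["sickled_fraction"]) >= 0).all()


def test_cumulative_curve_all_censored_identically_zero():
    curve = cumulative_curve(timelines([np.inf] * 5))
    assert (curve["sickled_fraction"] == 0).all()


def test_summary_hand_arithmetic():
    tl = timelines([5.333333, 6.4, 7.466667, np.inf, np.inf, np.inf])
    s = kinetics_summary(tl)
    assert s.pct_sickled == pytest.approx(0.5)
    assert s.median_time_min == pytest.approx(6.4)
    assert s.delay_min == pytest.approx(5.333333)
    assert s.max_rate_per_sec == pytest.approx((1 / 6) / 64, rel=1e-6)


def test_summary_single_event():
    s = kinetics_summary(timelines([10.0]))
    assert s.pct_sickled == 1.0
    assert s.median_time_min == s.delay_min == 10.0


def test_summary_consistent_with_curve():
    tl = timelines([4.3, 5.2, 9.1, np.inf, 12.0, np.inf, np.inf])
    s = kinetics_summary(tl)
    curve = cumulative_curve(tl)
    assert curve["sickled_fraction"].iloc[-1] == pytest.approx(s.pct_sickled)
    assert s.delay_min <= s.median_time_min
    assert s.max_rate_per_sec >= s.pct_sickled / (30 * 60)


def test_empty_timelines_rejected():
    import pandas as pd

    with pytest.raises(ValueError):
        kinetics_summary(pd.DataFrame(columns=["time_min", "censored"]))


def test_summary_recovers_truncated_exponential_median():
    p_s, lam, t0 = 0.54, 0.165, 4.3
    cfg = KineticsConfig(n_cells=5000, susceptible_fraction=p_s, delay_min=t0, hazard_per_min=lam, seed=12)
    truth = simulate_sickling_times(cfg)
    obs = truth.loc[~truth["censored"], "true_time_min"]
    tl = timelines(list(obs) + [np.inf] * int(truth["censored"].sum()))
    s = kinetics_summary(tl)
    # closed-form conditional median of the truncated shifted exponential
    q = 1 - np.exp(-lam * (30 - t0))
    model_median = t0 - np.log(1 - 0.5 * q) / lam
    assert s.median_time_min == pytest.approx(model_median, abs=256 / 4 / 60)


# --------------------------------------------------------- group comparisons


def test_gbw_identical_groups():
    tl = timelines([1, 2, np.inf])
    res = gehan_breslow_wilcoxon(tl, tl)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_gbw_matches_hand_worked_example():
    # A events {1,2}, B {3,4}: U = 4*0.5 + 3*(2/3) = 4; V = 4 + 2 = 6
    res = gehan_breslow_wilcoxon(timelines([1, 2]), timelines([3, 4]))
    assert res.statistic == pytest.approx(16.0 / 6.0)
    assert res.p_value == pytest.approx(0.1024704, abs=1e-6)


def test_gbw_agrees_with_independent_survival_library():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(3)
    ta = np.minimum(4 + rng.exponential(6, 80), 30.0)
    tb = np.minimum(4 + rng.exponential(9, 90), 30.0)
    ea, eb = ta < 30, tb < 30
    res = gehan_breslow_wilcoxon(
        timelines(np.where(ea, ta, np.inf)), timelines(np.where(eb, tb, np.inf))
    )
    ref = lifelines.statistics.logrank_test(ta, tb, ea, eb, weightings="wilcoxon")
    assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


def test_gbw_no_events_gives_null_result():
    res = gehan_breslow_wilcoxon(timelines([np.inf] * 5), timelines([np.inf] * 5))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_wilcoxon_identical_samples():
    res = wilcoxon_times([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.p_value == pytest.approx(1.0, abs=1e-6)


def test_wilcoxon_matches_exhaustive_enumeration():
    a, b = [1, 2, 3], [4, 5, 6]
    res = wilcoxon_times(a, b)
    # enumerate all 20 assignments of ranks to group A
    pooled = sorted(a + b)
    observed = sum(sorted(pooled).index(x) + 1 for x in a)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, 7), 3):
        total += 1
        s = sum(combo)
        if abs(s - 10.5) >= abs(observed - 10.5):  # two-sided
            count += 1
    assert res.p_value == pytest.approx(count / total)  # = 0.1


def test_wilcoxon_power_under_grid_shift():
    rng = np.random.default_rng(4)
    grid = 64 / 60
    hits = 0
    reps = 200
    for _ in range(reps):
        a = np.ceil((4.3 + rng.exponential(6, 150)) / grid) * grid
        b = a[:150] + 2 * grid
        hits += wilcoxon_times(a, rng.permutation(b)).p_value < 0.001
    assert hits / reps >= 0.95


def test_wilcoxon_empty_group_rejected():
    with pytest.raises(ValueError):
        wilcoxon_times([], [1.0])
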