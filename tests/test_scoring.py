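"""Fisher's discriminant, Sickle Score, gate calibration, endpoints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sicklekit.morphometry import featurize
from sicklekit.scoring import (
    calibrate_sickle_gate,
    compare_groups_t,
    fishers_discriminant,
    percent_sickled,
    rank_metrics,
    sickle_score,
)
from sicklekit.simulate.shapes import ShapeParams, render_cell

# ------------------------------------------------------------------------- Fd


def test_fd_hand_arithmetic():
    assert fishers_discriminant([1, 2, 3], [4, 6, 8]) == pytest.approx(4.0 / 3.0)


def test_fd_identity_is_zero():
    assert fishers_discriminant([1, 2, 3], [1, 2, 3]) == 0.0


def test_fd_recovers_population_value():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 100_000)
    b = rng.normal(1, 1, 100_000)
    assert fishers_discriminant(a, b) == pytest.approx(0.5, abs=0.01)


def test_fd_constant_samples():
    assert fishers_discriminant([2, 2], [2, 2]) == 0.0
    assert fishers_discriminant([2, 2], [3, 3]) == float("inf")


def test_fd_small_sample_rejected():
    with pytest.raises(ValueError):
        fishers_discriminant([1], [2, 3])


@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=30),
    st.lists(st.floats(-100, 100), min_size=3, max_size=30),
    st.floats(0.1, 10),
    st.floats(-50, 50),
)
def test_fd_symmetry_and_affine_invariance(a, b, scale, shift):
    fd_ab = fishers_discriminant(a, b)
    assert fd_ab == fishers_discriminant(b, a)
    if np.isfinite(fd_ab):
        a2 = [scale * x + shift for x in a]
        b2 = [scale * x + shift for x in b]
        assert fishers_discriminant(a2, b2) == pytest.approx(fd_ab, rel=1e-6, abs=1e-9)


def test_ranking_of_table_against_itself_all_zero(training_sets):
    rk = rank_metrics(training_sets["sickle"], training_sets["sickle"])
    assert all(v == 0.0 for _, v in rk.ranking)


def test_ranking_sorted_descending_with_alphabetical_ties(training_sets):
    rk = rank_metrics(training_sets["sickle"], training_sets["non_sickle"])
    values = [v for _, v in rk.ranking]
    assert values == sorted(values, reverse=True)


def test_missing_metric_rejected_by_name(training_sets):
    with pytest.raises(ValueError, match="nope"):
        rank_metrics(training_sets["sickle"], training_sets["non_sickle"], ["nope"])


# ---------------------------------------------------------------- SickleScore


def test_score_division():
    rec = {"symmetry2": 0.8, "shape_ratio": 0.2}
    assert sickle_score(rec) == pytest.approx(4.0)


def test_circle_scores_near_zero():
    ev = render_cell(ShapeParams.for_class("disc"), seed=1, crop_px=64)
    assert featurize(ev)["sickle_score"] < 0.1


def test_flagged_or_nonpositive_ratio_gives_nan():
    assert np.isnan(sickle_score({"symmetry2": 0.5, "shape_ratio": 0.0}))
    assert np.isnan(sickle_score({"symmetry2": 0.5, "shape_ratio": 0.5, "degenerate": True}))
    table = pd.DataFrame(
        {"symmetry2": [0.5, 0.5], "shape_ratio": [0.5, 0.5], "degenerate": [False, True]}
    )
    out = sickle_score(table)
    assert out.iloc[0] == 1.0 and np.isnan(out.iloc[1])


def test_score_increases_with_crescent_elongation():
    medians = []
    for e in (1.5, 2.0, 2.5, 3.0, 3.5, 4.0):
        scores = [
            featurize(render_cell(ShapeParams.for_class("crescent", elongation=e), seed=k, crop_px=80))["sickle_score"]
            for k in range(50)
        ]
        medians.append(np.median(scores))
    assert all(np.diff(medians) > 0)


def test_crescents_outscore_discs_for_every_paired_seed():
    for seed in range(200):
        c = featurize(render_cell(ShapeParams.for_class("crescent"), seed=seed, crop_px=80))
        d = featurize(render_cell(ShapeParams.for_class("disc"), seed=seed, crop_px=80))
        assert c["sickle_score"] > d["sickle_score"]


# ----------------------------------------------------------------------- gate


def test_gate_threshold_linear_interpolation_quantile():
    gate = calibrate_sickle_gate(np.arange(1, 101, dtype=float), spillover=0.10)
    assert gate.threshold == pytest.approx(90.1)
    assert percent_sickled(np.arange(1, 101, dtype=float), gate) == pytest.approx(0.10)


def test_constant_scores_flag_degenerate_gate():
    gate = calibrate_sickle_gate(np.full(200, 3.0), spillover=0.10)
    assert gate.degenerate
    assert gate.threshold == 3.0
    assert percent_sickled(np.full(200, 3.0), gate) == 0.0  # strict inequality


def test_held_out_spillover_consistency():
    rng = np.random.default_rng(1)
    cal = rng.lognormal(0, 0.5, 10_000)
    held = rng.lognormal(0, 0.5, 10_000)
    gate = calibrate_sickle_gate(cal, spillover=0.10)
    assert percent_sickled(held, gate) == pytest.approx(0.10, abs=0.01)


def test_too_few_scores_rejected():
    with pytest.raises(ValueError):
        calibrate_sickle_gate(np.arange(50, dtype=float))


def test_percent_sickled_arithmetic_and_empty_rejection():
    gate = calibrate_sickle_gate(np.arange(1, 101, dtype=float), spillover=0.10)
    scores = np.array([1, 2, 3, 4, 5, 6, 7, 95, 96, 97], dtype=float)
    assert percent_sickled(scores, gate) == pytest.approx(0.30)
    with pytest.raises(ValueError):
        percent_sickled(np.array([np.nan, np.nan]), gate)


# -------------------------------------------------------------------- t tests


def test_t_test_separated_groups_significant():
    res = compare_groups_t([34, 35, 36], [29, 30, 31])
    assert res.p_value < 0.05
    assert res.mean_a == pytest.approx(35)


def test_t_test_identical_groups_p_one():
    res = compare_groups_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_t_test_type_i_error_calibrated():
    rng = np.random.default_rng(2)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        a = rng.normal(30, 2, 5)
        b = rng.normal(30, 2, 5)
        rejections += compare_groups_t(a, b).p_value < 0.05
    assert abs(rejections / reps - 0.05) <= 0.02


def test_t_test_needs_two_trials():
    with pytest.raises(ValueError):
        compare_groups_t([1.0], [2.0, 3.0])
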