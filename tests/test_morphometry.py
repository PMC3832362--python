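"""Morphometry: segmentation, shape metrics, symmetry, texture, focus."""

import numpy as np
import pytest
from skimage import draw

from sicklekit.morphometry import (
    ImageEvent,
    ObjectMask,
    _boundary_radii,
    featurize,
    featurize_events,
    focus_score,
    segment_event,
    shape_features,
    symmetry2,
    texture_features,
)
from sicklekit.simulate.shapes import ShapeParams, render_cell


def _mask(shape_px, draw_fn):
    m = np.zeros((shape_px, shape_px), dtype=bool)
    rr, cc = draw_fn()
    m[rr, cc] = True
    return m


def circle_mask(d, n=None):
    n = n or int(d) + 20
    return _mask(n, lambda: draw.disk(((n - 1) / 2, (n - 1) / 2), d / 2))


def ellipse_mask(a, b, n=None):
    n = n or 2 * a + 20
    return _mask(n, lambda: draw.ellipse((n - 1) / 2, (n - 1) / 2, b, a))


# ---------------------------------------------------------------- segmentation


def test_rendered_disc_segments_to_expected_area():
    ev = render_cell(ShapeParams.for_class("disc"), seed=2, crop_px=64, pixel_size_um=0.2)
    obj = segment_event(ev)  # 8 um disc at 0.2 um/px -> radius 20 px
    expected = np.pi * 20.0**2
    assert abs(obj.area_px - expected) / expected < 0.10


def test_blank_crop_flagged_degenerate_not_crashed():
    rng = np.random.default_rng(0)
    ev = ImageEvent("blank", {"brightfield": 0.8 + rng.normal(0, 0.02, (64, 64))}, 0.5)
    obj = segment_event(ev)
    assert obj.degenerate
    rec = featurize(ev)
    assert rec["degenerate"] and np.isnan(rec["shape_ratio"])


def test_aggregate_segments_to_single_component():
    from scipy import ndimage as ndi

    ev = render_cell(ShapeParams.for_class("aggregate"), seed=4, crop_px=80)
    obj = segment_event(ev)
    assert not obj.degenerate
    assert ndi.label(obj.mask)[1] == 1


def test_missing_channel_rejected():
    ev = render_cell(ShapeParams.for_class("disc"), seed=0, crop_px=64)
    with pytest.raises(ValueError, match="nope"):
        segment_event(ev, channel="nope")


# ------------------------------------------------------------- shape features


def test_circle_length_and_shape_ratio():
    f = shape_features(ObjectMask(circle_mask(40), "bf"), 1.0)
    assert abs(f["length_um"] - 40) <= 1.0
    assert f["shape_ratio"] >= 0.9


def test_rounded_rectangle_dimensions_match_pixel_oracle():
    # stadium 100x20: flat medial profile, Tmin = Tmax = 20
    n, L, w = 140, 100, 20
    m = np.zeros((n, n), dtype=bool)
    r = w / 2
    cy = (n - 1) / 2
    m[int(cy - r) + 1 : int(cy + r), (n - L) // 2 + int(r) : (n + L) // 2 - int(r)] = True
    for cx in ((n - L) // 2 + r, (n + L) // 2 - r):
        rr, cc = draw.disk((cy, cx - 0.5), r)
        m[rr, cc] = True
    f = shape_features(ObjectMask(m, "bf"), 1.0)
    assert abs(f["length_um"] - 100) <= 3
    assert abs(f["thickness_min_um"] - 20) <= 3
    assert abs(f["shape_ratio"] - 0.2) <= 0.04


def test_crescent_shape_ratio_below_matched_disc_every_seed():
    for seed in range(100):
        c = render_cell(ShapeParams.for_class("crescent"), seed=seed, crop_px=80)
        d = render_cell(ShapeParams.for_class("disc"), seed=seed, crop_px=80)
        assert featurize(c)["shape_ratio"] < featurize(d)["shape_ratio"]


def test_scale_covariance_of_physical_measures():
    obj = ObjectMask(ellipse_mask(30, 15), "bf")
    f1 = shape_features(obj, 1.0)
    f2 = shape_features(obj, 2.0)
    assert f2["length_um"] == pytest.approx(2 * f1["length_um"])
    assert f2["thickness_min_um"] == pytest.approx(2 * f1["thickness_min_um"])
    assert f2["area_um2"] == pytest.approx(4 * f1["area_um2"])
    assert f2["shape_ratio"] == pytest.approx(f1["shape_ratio"])
    assert f2["circularity"] == pytest.approx(f1["circularity"])


def test_rotation_robustness():
    # length and symmetry on a rendered crescent; Tmin additionally on a
    # flat-profile shape (at ~5 px thickness the EDT minimum is
    # quantization-limited, so thin shapes cannot meet a 2% bound)
    ev = render_cell(ShapeParams.for_class("crescent"), seed=11, crop_px=80)
    obj = segment_event(ev)
    rot = ObjectMask(np.rot90(obj.mask).copy(), "bf")
    f0 = shape_features(obj, 0.5)
    f90 = shape_features(rot, 0.5)
    assert abs(f90["length_um"] - f0["length_um"]) / f0["length_um"] < 0.02
    assert abs(symmetry2(rot) - symmetry2(obj)) < 0.02

    n, L, w = 140, 90, 24  # stadium: flat medial profile
    m = np.zeros((n, n), dtype=bool)
    r = w / 2
    cy = (n - 1) / 2
    m[int(cy - r) + 1 : int(cy + r), (n - L) // 2 + int(r) : (n + L) // 2 - int(r)] = True
    for cx in ((n - L) // 2 + r, (n + L) // 2 - r):
        rr, cc = draw.disk((cy, cx - 0.5), r)
        m[rr, cc] = True
    f_a = shape_features(ObjectMask(m, "bf"), 1.0)
    f_b = shape_features(ObjectMask(np.rot90(m).copy(), "bf"), 1.0)
    assert abs(f_b["thickness_min_um"] - f_a["thickness_min_um"]) / f_a["thickness_min_um"] < 0.02
    assert abs(f_b["length_um"] - f_a["length_um"]) / f_a["length_um"] < 0.02


# ------------------------------------------------------------------- symmetry


def test_circle_symmetry_is_negligible():
    assert symmetry2(ObjectMask(circle_mask(40), "bf")) <= 0.02


def test_ellipse_symmetry_matches_fourier_oracle():
    a, b = 60, 30
    s2 = symmetry2(ObjectMask(ellipse_mask(a, b), "bf"))
    theta = np.arange(256) * 2 * np.pi / 256
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    coeffs = np.fft.fft(r)
    oracle = np.abs(coeffs[2]) / np.abs(coeffs[0])
    assert s2 == pytest.approx(oracle, abs=1e-3)


def test_symmetry_monotone_in_axis_ratio():
    s_circle = symmetry2(ObjectMask(circle_mask(60), "bf"))
    s_e2 = symmetry2(ObjectMask(ellipse_mask(40, 20), "bf"))
    s_e3 = symmetry2(ObjectMask(ellipse_mask(45, 15), "bf"))
    assert s_e3 > s_e2 > s_circle


def test_concave_boundary_uses_outer_radius():
    # crescent: rays crossing the concavity must take the outer crossing
    ev = render_cell(ShapeParams.for_class("crescent", curvature=0.9), seed=1, crop_px=80)
    obj = segment_event(ev)
    radii = _boundary_radii(obj.mask)
    assert radii.max() > 0
    assert np.isfinite(radii).all()


# -------------------------------------------------------------------- texture


def test_checkerboard_cooccurrence_between_extreme_levels():
    img = np.full((40, 40), 0.5)
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:30, 10:30] = True
    yy, xx = np.mgrid[0:40, 0:40]
    img[mask] = np.where(((yy + xx) % 2 == 0)[mask], 0.2, 0.8)
    ev = ImageEvent("cb", {"brightfield": img}, 0.5)
    contrast, entropy = texture_features(ev, ObjectMask(mask, "brightfield"))
    assert contrast == pytest.approx(225.0)
    assert entropy == pytest.approx(1.0)


def test_constant_interior_has_zero_texture():
    ev = ImageEvent("c", {"brightfield": np.full((40, 40), 0.5)}, 0.5)
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:30, 10:30] = True
    assert texture_features(ev, ObjectMask(mask, "brightfield")) == (0.0, 0.0)


def test_noise_strictly_increases_texture_metrics():
    mask = np.zeros((40, 40), dtype=bool)
    mask[8:32, 8:32] = True
    base = np.full((40, 40), 0.5)
    for seed in range(100):
        rng = np.random.default_rng(seed)
        noisy = base + rng.normal(0, 0.05, base.shape)
        c, e = texture_features(ImageEvent("n", {"brightfield": noisy}, 0.5), ObjectMask(mask, "brightfield"))
        assert c > 0 and e > 0


# ---------------------------------------------------------------------- focus


def test_defocus_lowers_focus_score():
    sharp = render_cell(ShapeParams.for_class("disc"), seed=1, crop_px=64)
    blurred = render_cell(ShapeParams.for_class("disc", defocus_sigma_px=3.0), seed=1, crop_px=64)
    assert focus_score(sharp) > focus_score(blurred)


def test_focus_score_invariant_to_intensity_scaling():
    ev = render_cell(ShapeParams.for_class("disc"), seed=2, crop_px=64)
    doubled = ImageEvent("x", {"brightfield": 2.0 * ev.channels["brightfield"]}, 0.5)
    assert focus_score(ev) == pytest.approx(focus_score(doubled), rel=1e-6)


def test_blank_crop_scores_below_in_focus_cells():
    rng = np.random.default_rng(3)
    blank = focus_score(ImageEvent("b", {"brightfield": 0.8 + rng.normal(0, 0.02, (64, 64))}, 0.5))
    cells = [
        focus_score(render_cell(ShapeParams.for_class("disc"), seed=s, crop_px=64))
        for s in range(100)
    ]
    assert blank < min(cells)


# ------------------------------------------------------------------ featurize


def test_featurize_batch_conserves_rows_and_flags_only_degenerates():
    events = [render_cell(ShapeParams.for_class("disc"), seed=s, crop_px=64, event_id=f"d{s}") for s in range(5)]
    rng = np.random.default_rng(0)
    events.append(ImageEvent("blank", {"brightfield": 0.8 + rng.normal(0, 0.02, (64, 64)), "dna": np.zeros((64, 64)), "marker": np.zeros((64, 64))}, 0.5))
    table = featurize_events(events)
    assert len(table) == 6
    assert table["degenerate"].sum() == 1
    assert table.loc[~table["degenerate"], "shape_ratio"].ge(0.9).all()
    assert np.isfinite(table.loc[~table["degenerate"], ["h_contrast", "h_entropy"]]).all().all()


def test_featurize_requires_brightfield():
    ev = ImageEvent("x", {"dna": np.zeros((32, 32))}, 0.5)
    with pytest.raises(ValueError, match="brightfield"):
        featurize(ev)
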