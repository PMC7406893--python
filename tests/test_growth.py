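"""Growth imaging: generator, segmentation, tracing, ordering metric, stats."""

import numpy as np
import pandas as pd
import pytest

from neuropillar.growth import (
    ArrayImage,
    analyze_image,
    fractional_separation,
    growth_stats,
    ordered_fraction,
    polyline_length,
    resample_polyline,
    segment_and_skeletonize,
    synth_array_image,
    trace_neurites,
    GrowthMetrics,
)


# ------------------------------------------------------- fractional separation

def test_fractional_separation_values():
    assert fractional_separation(2.0, 0.2) == pytest.approx(0.9)
    assert fractional_separation(2.0, 0.0) == 1.0
    assert fractional_separation(2.0, 2.0 - 1e-9) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        fractional_separation(0.2, 2.0)


# ----------------------------------------------------------- ordered fraction

def segments_at(angles_deg, length=10.0):
    out = []
    for a in np.atleast_1d(angles_deg):
        a = np.deg2rad(a)
        out.append(np.array([[0.0, 0.0], [np.sin(a), np.cos(a)]]) * length)
    return out


def test_all_rows_fully_ordered():
    assert ordered_fraction(segments_at([0.0] * 5)) == 1.0
    assert ordered_fraction(segments_at([90.0] * 5)) == 1.0


def test_diagonal_segments_unordered():
    assert ordered_fraction(segments_at([45.0] * 5), theta_tol=10.0) == 0.0


def test_isotropic_orientations_match_uniform_measure():
    """Uniform orientations: ordered fraction -> 4*theta_tol/180 = 0.222."""
    rng = np.random.default_rng(7)
    polys = segments_at(rng.uniform(0, 180, 20000))
    f = ordered_fraction(polys, theta_tol=10.0)
    assert f == pytest.approx(4 * 10 / 180, abs=0.01)


def test_rotation_invariance():
    rng = np.random.default_rng(3)
    angles = rng.uniform(0, 180, 500)
    f0 = ordered_fraction(segments_at(angles), row_axis_deg=0.0)
    rot = 33.0
    f1 = ordered_fraction(segments_at(angles + rot), row_axis_deg=rot)
    assert f1 == pytest.approx(f0, abs=1e-12)


def test_zero_length_reported_missing():
    assert ordered_fraction([]) is None
    assert ordered_fraction([np.array([[0.0, 0.0]])]) is None
    with pytest.raises(ValueError):
        ordered_fraction(segments_at([0.0]), theta_tol=60.0)


def test_resample_polyline_preserves_endpoints_and_length():
    p = np.array([[0, 0], [0, 10], [10, 10]], dtype=float)
    q = resample_polyline(p, 2.0)
    assert np.allclose(q[0], p[0]) and np.allclose(q[-1], p[-1])
    assert polyline_length(q) == pytest.approx(polyline_length(p), rel=0.05)


# -------------------------------------------------------------------- tracing

def test_trace_straight_line_single_path():
    skel = np.zeros((20, 20), dtype=bool)
    skel[10, 2:18] = True
    paths = trace_neurites(skel)
    assert len(paths) == 1
    assert polyline_length(paths[0]) == pytest.approx(15.0)
    f = ordered_fraction(paths)
    assert f == 1.0


def test_trace_x_junction_four_paths():
    skel = np.zeros((21, 21), dtype=bool)
    for i in range(21):
        skel[i, i] = True
        skel[i, 20 - i] = True
    paths = trace_neurites(skel)
    assert len(paths) == 4
    # each arm runs from the centre to a corner
    lengths = sorted(polyline_length(p) for p in paths)
    assert all(abs(l - lengths[0]) < 3 for l in lengths)


def test_traced_length_equals_adjacency_length():
    """Total traced length = 8-connectivity pixel-step length (1 or sqrt2)."""
    rng = np.random.default_rng(5)
    arr, truth, _ = synth_array_image(n_neurites=8, seed=11)
    skel, _ = segment_and_skeletonize(arr)
    total = sum(polyline_length(p) for p in skel.polylines)
    # independent count over the skeleton pixels
    from skimage.morphology import skeletonize
    from skimage.filters import threshold_otsu

    mask = arr.image > threshold_otsu(arr.image)
    from neuropillar.growth import _remove_small

    sk = skeletonize(_remove_small(mask, 30))
    pix = set(map(tuple, np.argwhere(sk)))
    length = 0.0
    for (r, c) in pix:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            if (r + dr, c + dc) in pix:
                length += np.hypot(dr, dc)
    # tracing may drop a few junction-adjacent steps
    assert total == pytest.approx(length, rel=0.03)


# --------------------------------------------------------------- segmentation

def test_blank_image_empty_skeleton():
    img = ArrayImage(image=np.zeros((64, 64)))
    with pytest.warns(UserWarning, match="empty"):
        skel, mask = segment_and_skeletonize(img, threshold=0.5)
    assert skel.polylines == []
    assert not mask.any()


def test_straight_bar_recovers_length():
    img_arr = np.zeros((40, 80))
    img_arr[18:23, 10:70] = 1.0  # 5-px-wide, 60-px-long bar
    skel, mask = segment_and_skeletonize(
        ArrayImage(image=img_arr), threshold=0.5, min_object_px=10
    )
    assert len(skel.polylines) == 1
    # thinning erodes about half the bar width at each end
    assert polyline_length(skel.polylines[0]) == pytest.approx(60, abs=6)


def test_skeleton_length_close_to_truth():
    arr, truth, _ = synth_array_image(seed=3)
    skel, _ = segment_and_skeletonize(arr)
    truth_len = sum(polyline_length(p) for p in truth)
    assert skel.total_length / arr.pixel_size == pytest.approx(
        truth_len, rel=0.10
    )


def test_min_object_filter_monotonicity():
    """Raising the small-object cutoff never increases skeleton length."""
    arr, _, _ = synth_array_image(n_neurites=12, seed=9)
    lengths = []
    for min_px in (10, 50, 200, 1000):
        skel, _ = segment_and_skeletonize(arr, min_object_px=min_px)
        lengths.append(skel.total_length)
    assert all(a >= b for a, b in zip(lengths, lengths[1:]))


# ------------------------------------------------------------------ generator

def test_generator_deterministic():
    a1, t1, f1 = synth_array_image(seed=42)
    a2, t2, f2 = synth_array_image(seed=42)
    assert np.array_equal(a1.image, a2.image)
    assert all(np.array_equal(x, y) for x, y in zip(t1, t2))


def test_generator_validates_inputs():
    with pytest.raises(ValueError):
        synth_array_image(aligned_fraction=1.5)
    with pytest.raises(ValueError):
        synth_array_image(pitch=0.1, diameter=200.0)


def test_fully_aligned_cohort_measures_near_one():
    vals = [
        analyze_image(synth_array_image(aligned_fraction=1.0, seed=s)[0]).ordered
        for s in range(3)
    ]
    assert np.mean(vals) >= 0.95


def test_half_aligned_recovered_within_tolerance():
    """aligned_fraction = 0.5 recovered within +/-0.05 over 10 seeds."""
    vals = [
        analyze_image(synth_array_image(aligned_fraction=0.5, seed=s)[0]).ordered
        for s in range(10)
    ]
    assert abs(np.mean(vals) - 0.5) < 0.05


def test_alignment_sweep_recovery():
    """Mean |measured - dialled| < 0.07 over the aligned-fraction grid."""
    errs = []
    for af in (0.0, 0.25, 0.5, 0.75, 1.0):
        vals = [
            analyze_image(
                synth_array_image(aligned_fraction=af, seed=s)[0]
            ).ordered
            for s in range(3)
        ]
        errs.append(abs(np.mean(vals) - af))
    assert np.mean(errs) < 0.07


# ---------------------------------------------------------------------- stats

def test_identical_arrays_zero_standard_error():
    metrics = [GrowthMetrics(0.3, 0.4, 2.0, 200.0) for _ in range(4)]
    out = growth_stats(metrics, by="pitch")
    assert out["ordered_se"].iloc[0] == pytest.approx(0.0)
    assert out["n"].iloc[0] == 4


def test_two_array_standard_error_hand_computed():
    metrics = [
        GrowthMetrics(0.3, 0.36, 2.0, 200.0),
        GrowthMetrics(0.3, 0.40, 2.0, 200.0),
    ]
    out = growth_stats(metrics, by="pitch")
    assert out["ordered_mean"].iloc[0] == pytest.approx(0.38)
    assert out["ordered_se"].iloc[0] == pytest.approx(0.02)


def test_singleton_group_missing_se():
    metrics = [
        GrowthMetrics(0.3, 0.4, 2.0, 200.0),
        GrowthMetrics(0.2, 0.1, 3.0, 200.0),
    ]
    out = growth_stats(metrics, by="pitch")
    assert out["ordered_se"].isna().all()


def test_group_recovery_from_synthetic_cohort():
    """Known group means are recovered within their standard errors."""
    rows = []
    rng = np.random.default_rng(0)
    for pitch, target in ((2.0, 0.6), (4.0, 0.2)):
        for s in range(3):
            arr, _, _ = synth_array_image(
                pitch=pitch, aligned_fraction=target,
                seed=int(rng.integers(0, 1000)),
            )
            m = analyze_image(arr)
            rows.append(
                {"pitch": pitch, "diameter": 200.0,
                 "total_growth": m.total_growth, "ordered": m.ordered}
            )
    out = growth_stats(pd.DataFrame(rows), by="pitch")
    for pitch, target in ((2.0, 0.6), (4.0, 0.2)):
        row = out[out.pitch == pitch].iloc[0]
        band = max(3 * row["ordered_se"], 0.06)
        assert abs(row["ordered_mean"] - target) < band


def test_grouping_by_fractional_separation():
    metrics = [
        GrowthMetrics(0.3, 0.4, 2.0, 200.0),
        GrowthMetrics(0.2, 0.3, 4.0, 400.0),
    ]
    out = growth_stats(metrics, by="fractional_separation")
    assert set(np.round(out["fractional_separation"], 3)) == {0.9}
    assert out["n"].iloc[0] == 2
    with pytest.raises(ValueError):
        growth_stats(metrics, by="colour")
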