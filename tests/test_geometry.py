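"""Morphometry operators against analytic phantoms and brute-force oracles."""

import numpy as np
import pytest

from opgpred.errors import EmptyRegionError, GeometryError, UndefinedRatioError
from opgpred.geometry import (
    RegionMask,
    StreamlineSet,
    compute_morphology,
    compute_perimeter,
    compute_thickness,
    compute_tortuosity_index,
    compute_volume,
    filter_streamlines,
    streamlines_to_mask,
)

from conftest import digital_cylinder, digital_disk


# ---------------------------------------------------------------------------
# volume


def test_volume_is_exact_count_times_voxel_volume():
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask.ravel()[:50] = True
    rm = RegionMask(mask=mask, label="ON-L", spacing_mm=(2, 2, 2))
    assert compute_volume(rm) == 50 * 8.0

    one = np.zeros((5, 5, 5), dtype=bool)
    one[2, 2, 2] = True
    assert compute_volume(RegionMask(one, "ON-L", (1, 1, 1))) == 1.0


def test_volume_of_digital_cylinder_matches_analytic():
    cyl = digital_cylinder(radius_mm=5.0, length_vox=20)
    analytic = np.pi * 25 * 20  # pi r^2 L
    assert compute_volume(cyl) == pytest.approx(analytic, rel=0.15)


def test_volume_empty_mask_raises():
    rm = RegionMask(np.zeros((4, 4, 4), dtype=bool), "ON-L", (1, 1, 1))
    with pytest.raises(EmptyRegionError):
        compute_volume(rm)


# ---------------------------------------------------------------------------
# perimeter


def test_perimeter_of_solid_square_is_boundary_walk_length():
    # 5x5 solid square: 16 boundary pixels, every contour step has length 1
    sq = np.zeros((9, 9), dtype=bool)
    sq[2:7, 2:7] = True
    assert compute_perimeter(sq, (1.0, 1.0)) == pytest.approx(16.0)


def test_perimeter_single_voxel_degenerates_to_zero():
    m = np.zeros((5, 5), dtype=bool)
    m[2, 2] = True
    assert compute_perimeter(m, (1.0, 1.0)) == 0.0


def _oracle_convex_perimeter(sl: np.ndarray) -> float:
    """Independent walk: order boundary pixels by polar angle (convex shapes)."""
    from scipy import ndimage

    boundary = sl & ~ndimage.binary_erosion(
        sl, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    pts = np.argwhere(boundary).astype(float)
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 0] - c[0], pts[:, 1] - c[1])
    ordered = pts[np.argsort(ang)]
    closed = np.vstack([ordered, ordered[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def test_perimeter_of_digital_disk_matches_brute_force_walk():
    disk = digital_disk(10)
    p = compute_perimeter(disk, (1.0, 1.0))
    assert p == pytest.approx(_oracle_convex_perimeter(disk), rel=0.10)


def test_perimeter_sums_over_components_and_rejects_empty():
    two = np.zeros((10, 10), dtype=bool)
    two[1:4, 1:4] = True  # 3x3 square: 8 boundary pixels, perimeter 8
    two[6:9, 6:9] = True
    assert compute_perimeter(two, (1.0, 1.0)) == pytest.approx(16.0)
    with pytest.raises(EmptyRegionError):
        compute_perimeter(np.zeros((4, 4), dtype=bool), (1.0, 1.0))


def test_perimeter_scales_linearly_area_quadratically_under_upsampling():
    # the same physical disk digitized at 2x resolution
    disk = digital_disk(8)
    up = digital_disk(16)
    p1, p2 = compute_perimeter(disk, (1, 1)), compute_perimeter(up, (1, 1))
    assert p2 == pytest.approx(2 * p1, rel=0.05)
    assert up.sum() == pytest.approx(4 * disk.sum(), rel=0.05)


# ---------------------------------------------------------------------------
# thickness


def test_thickness_of_cylinder_within_one_voxel_of_radius():
    cyl = digital_cylinder(radius_mm=4.0, length_vox=10)
    samples = compute_thickness(cyl)
    assert abs(samples.mean() - 4.0) <= 0.5


def test_thickness_of_one_voxel_line_is_degenerate():
    m = np.zeros((7, 7, 10), dtype=bool)
    m[3, 3, :] = True
    samples = compute_thickness(RegionMask(m, "ON-L", (1, 1, 1)))
    assert np.all(samples <= np.sqrt(2) / 2 + 1e-12)


def test_thickness_increases_with_tube_radius():
    t3 = compute_thickness(digital_cylinder(3.0, 10)).mean()
    t5 = compute_thickness(digital_cylinder(5.0, 10)).mean()
    assert t5 > t3


# ---------------------------------------------------------------------------
# tortuosity


def test_tortuosity_index_examples():
    assert compute_tortuosity_index(100.0, 40.0) == 2.5
    with pytest.raises(UndefinedRatioError):
        compute_tortuosity_index(10.0, 0.0)


def test_tortuosity_smaller_for_more_convoluted_equal_area_shape():
    # square vs 1-wide snake of equal area: snake has far more border
    square = np.zeros((20, 20), dtype=bool)
    square[2:6, 2:6] = True  # 16 px
    snake = np.zeros((20, 20), dtype=bool)
    snake[2, 2:18] = True  # 16 px, 1 wide
    a = 16.0
    t_sq = compute_tortuosity_index(a, compute_perimeter(square, (1, 1)))
    t_sn = compute_tortuosity_index(a, compute_perimeter(snake, (1, 1)))
    assert t_sn < t_sq


# ---------------------------------------------------------------------------
# invariances


def test_morphometry_invariant_under_axis_aligned_translation():
    base = digital_cylinder(3.0, 8)
    big = np.zeros((base.mask.shape[0] + 6, base.mask.shape[1] + 6, base.mask.shape[2] + 4), bool)
    big[1 : 1 + base.mask.shape[0], 2 : 2 + base.mask.shape[1], 3 : 3 + base.mask.shape[2]] = (
        base.mask
    )
    m0 = compute_morphology(base)
    m1 = compute_morphology(RegionMask(big, "ON-L", base.spacing_mm))
    assert m0.volume_mm3 == m1.volume_mm3
    assert m0.perimeter_mm == m1.perimeter_mm
    assert m0.tortuosity_index == m1.tortuosity_index
    assert m0.thickness_mm.mean == pytest.approx(m1.thickness_mm.mean)


def test_summary_stats_are_ordered(tiny_cohort):
    for subj in tiny_cohort[:2]:
        m = compute_morphology(subj.masks[0]["ON-L"])
        for stats in (m.perimeter_mm, m.thickness_mm, m.tortuosity_index):
            assert stats.min <= stats.mean <= stats.max
            assert stats.sd >= 0


# ---------------------------------------------------------------------------
# streamline filter and voxelization


def _brute_force_predicate(line, rois, spacing, shape):
    """Independent membership check: explicit per-segment sampling loop."""
    hits = {k: False for k in rois}
    step = 0.5 * min(spacing)
    pts = [line[0]]
    for p0, p1 in zip(line[:-1], line[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / step)))
        for t in range(1, n + 1):
            pts.append(p0 + (p1 - p0) * t / n)
    for p in pts:
        idx = np.floor(np.asarray(p) / np.asarray(spacing)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
            continue
        for k, roi in rois.items():
            if roi.mask[tuple(idx)]:
                hits[k] = True
    return hits["a"] and hits["b"] and not hits["c"]


def _three_rois(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
    def box(lo, hi, label):
        m = np.zeros(shape, dtype=bool)
        m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        return RegionMask(m, label, spacing)

    return (
        box((1, 1, 1), (5, 19, 19), "ROI-A"),
        box((15, 1, 1), (19, 19, 19), "ROI-B"),
        box((9, 9, 1), (11, 11, 19), "ROI-C"),
    )


def test_filter_keeps_a_and_b_drops_c():
    a, b, c = _three_rois()
    through = np.array([[2.5, 2.5, 2.5], [17.5, 2.5, 2.5]])  # A->B avoiding C
    via_c = np.array([[2.5, 9.5, 9.5], [10.5, 9.5, 9.5], [17.5, 9.5, 9.5]])  # hits C
    only_a = np.array([[2.5, 2.5, 2.5], [3.5, 3.5, 3.5]])
    kept = filter_streamlines(StreamlineSet([through, via_c, only_a]), a, b, c)
    assert kept.count == 1
    assert np.array_equal(kept.lines[0], through)


def test_filter_matches_brute_force_on_random_lines():
    a, b, c = _three_rois()
    rng = np.random.default_rng(11)
    lines = [rng.uniform(0, 20, size=(rng.integers(2, 6), 3)) for _ in range(100)]
    kept = filter_streamlines(StreamlineSet(lines), a, b, c)
    expected = [
        i
        for i, ln in enumerate(lines)
        if _brute_force_predicate(ln, {"a": a, "b": b, "c": c}, (1.0, 1.0, 1.0), (20, 20, 20))
    ]
    kept_ids = [i for i, ln in enumerate(lines) if any(ln is k for k in kept.lines)]
    assert kept_ids == expected


def test_filter_rejects_mismatched_grids():
    a, b, c = _three_rois()
    c_bad = RegionMask(np.zeros((10, 10, 10), bool), "ROI-C", (1, 1, 1))
    with pytest.raises(GeometryError):
        filter_streamlines(StreamlineSet([np.zeros((2, 3))]), a, b, c_bad)


def test_voxelization_of_axis_aligned_line():
    line = np.array([[0.5, 0.5, 0.5], [9.5, 0.5, 0.5]])  # crosses 10 voxels in x
    m = streamlines_to_mask(StreamlineSet([line]), (12, 4, 4), (1, 1, 1))
    assert m.n_voxels == 10
    assert m.mask[:10, 0, 0].all()


def test_voxelization_union_property():
    rng = np.random.default_rng(5)
    l1 = rng.uniform(0, 12, size=(4, 3))
    l2 = rng.uniform(0, 12, size=(4, 3))
    m12 = streamlines_to_mask(StreamlineSet([l1, l2]), (12, 12, 12), (1, 1, 1))
    m1 = streamlines_to_mask(StreamlineSet([l1]), (12, 12, 12), (1, 1, 1))
    m2 = streamlines_to_mask(StreamlineSet([l2]), (12, 12, 12), (1, 1, 1))
    assert np.array_equal(m12.mask, m1.mask | m2.mask)


def test_voxelization_empty_set_raises():
    with pytest.raises(EmptyRegionError):
        streamlines_to_mask(StreamlineSet([]), (4, 4, 4), (1, 1, 1))
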