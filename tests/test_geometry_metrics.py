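"""DSC, Hausdorff distances and surface Dice against brute-force oracles."""
import math

import numpy as np
import pytest

from dirqa.errors import GeometryError, NotEvaluableError, ValidationError
from dirqa.geometry_metrics import (
    SurfacePointSet,
    classify_agreement,
    compute_dsc,
    compute_hd,
    compute_hd95,
    compute_sdsc,
    directed_distances,
    extract_surface,
    geometric_report,
    pairwise_min_distances_bruteforce,
)

from conftest import box_mask, make_grid, mask_from_array, random_blob_mask


# ---------------------------------------------------------------- surfaces


def test_single_voxel_has_six_face_points(unit_grid):
    m = box_mask(unit_grid, (3, 3, 2), (4, 4, 3))
    surf = extract_surface(m)
    assert len(surf) == 6
    center = m.grid.index_to_mm(np.array([3.0, 3.0, 2.0]))
    offsets = np.abs(surf.points - center)
    # each face center is half a spacing away along exactly one axis
    assert np.all(np.sort(offsets, axis=1)[:, :2] == 0)
    assert np.allclose(np.sort(offsets, axis=1)[:, 2], 0.5)


def test_two_voxel_bar_has_ten_face_points(unit_grid):
    m = box_mask(unit_grid, (3, 3, 2), (5, 4, 3))
    assert len(extract_surface(m)) == 10


def test_surface_empty_for_degenerate_masks():
    grid = make_grid(shape=(4, 4, 4))
    assert extract_surface(mask_from_array(np.zeros(grid.shape), grid)).is_empty
    assert extract_surface(mask_from_array(np.ones(grid.shape), grid)).is_empty


def test_surface_points_lie_on_face_planes(rng):
    grid = make_grid(shape=(9, 9, 6), spacing=(1.3, 1.1, 2.5), origin=(3, -2, 7))
    m = random_blob_mask(rng, grid)
    surf = extract_surface(m)
    idx = grid.mm_to_index(surf.points)
    # each point has exactly one half-integer index (the face axis)
    frac = np.abs((idx * 2) - np.round(idx * 2))
    assert np.allclose(frac, 0, atol=1e-9)
    half = np.abs(idx - np.round(idx)) > 0.25
    assert np.all(half.sum(axis=1) == 1)


# ---------------------------------------------------------------- DSC


def test_dsc_identical_disjoint_and_half_overlap(unit_grid):
    grid = make_grid(shape=(20, 12, 12))
    a = box_mask(grid, (0, 0, 0), (10, 10, 10))
    b = box_mask(grid, (5, 0, 0), (15, 10, 10))
    assert compute_dsc(a, a) == 1.0
    assert compute_dsc(a, b) == pytest.approx(2 * 500 / 2000)
    c = box_mask(unit_grid, (0, 0, 0), (2, 2, 2))
    d = box_mask(unit_grid, (6, 6, 3), (8, 8, 5))
    assert compute_dsc(c, d) == 0.0


def test_dsc_empty_mask_policy(unit_grid):
    full = box_mask(unit_grid, (2, 2, 2), (5, 5, 4))
    empty = box_mask(unit_grid, (0, 0, 0), (0, 0, 0))
    assert compute_dsc(full, empty) == 0.0  # structure missing from one set
    assert math.isnan(compute_dsc(empty, empty))


def test_dsc_grid_mismatch_raises(unit_grid):
    other = make_grid(origin=(5, 0, 0))
    with pytest.raises(GeometryError):
        compute_dsc(
            box_mask(unit_grid, (0, 0, 0), (2, 2, 2)),
            box_mask(other, (0, 0, 0), (2, 2, 2)),
        )


def test_dsc_bounded_by_volume_ratio(rng, unit_grid):
    for _ in range(20):
        a = random_blob_mask(rng, unit_grid)
        b = random_blob_mask(rng, unit_grid)
        if a.is_empty or b.is_empty:
            continue
        bound = 2 * min(a.voxel_count, b.voxel_count) / (
            a.voxel_count + b.voxel_count
        )
        assert compute_dsc(a, b) <= bound + 1e-12


@pytest.mark.parametrize(
    "dsc,band",
    [
        (0.0, "no agreement"),
        (0.004, "no agreement"),  # rounds to 0.00
        (0.1, "none to slight"),
        (0.205, "fair"),  # rounds to 0.21
        (0.5, "moderate"),
        (0.7, "substantial"),
        (0.86, "almost perfect"),
        (1.0, "almost perfect"),
    ],
)
def test_agreement_bands(dsc, band):
    assert classify_agreement(dsc) == band


def test_agreement_band_out_of_range_raises():
    with pytest.raises(ValidationError):
        classify_agreement(1.2)


# ---------------------------------------------------------------- distances


def test_directed_distances_identity_and_empty(unit_grid):
    m = box_mask(unit_grid, (2, 2, 2), (6, 6, 4))
    surf = extract_surface(m)
    assert np.all(directed_distances(surf, surf).distances == 0.0)
    empty = SurfacePointSet(points=np.empty((0, 3)), label="e")
    with pytest.raises(NotEvaluableError):
        directed_distances(surf, empty)


def test_parallel_slab_interior_distances():
    grid = make_grid(shape=(30, 30, 8))
    a = box_mask(grid, (0, 0, 0), (30, 30, 1))
    b = box_mask(grid, (0, 0, 4), (30, 30, 5))  # faces 3 mm apart
    sa, sb = extract_surface(a), extract_surface(b)
    d = directed_distances(sa, sb).distances
    # interior points of the facing surface are exactly 3 mm away
    assert d.min() == pytest.approx(3.0)
    assert np.all(d >= 3.0 - 1e-9)
    assert np.allclose(d, pairwise_min_distances_bruteforce(sa, sb), atol=1e-9)


def test_distances_match_bruteforce_oracle_on_random_masks(rng):
    grid = make_grid(shape=(8, 9, 5), spacing=(1.1, 0.9, 2.5))
    for _ in range(10):
        a = random_blob_mask(rng, grid, label="a")
        b = random_blob_mask(rng, grid, label="b")
        sa, sb = extract_surface(a), extract_surface(b)
        if sa.is_empty or sb.is_empty:
            continue
        assert np.allclose(
            directed_distances(sa, sb).distances,
            pairwise_min_distances_bruteforce(sa, sb),
            atol=1e-6,
        )


# ---------------------------------------------------------------- HD / HD95


def test_hd95_identical_surfaces_zero(unit_grid):
    surf = extract_surface(box_mask(unit_grid, (2, 2, 1), (7, 7, 4)))
    assert compute_hd95(surf, surf) == 0.0
    assert compute_hd(surf, surf) == 0.0


def test_hd95_ignores_single_outlier_point():
    # 100 source points: 99 coincide with targets, one is 10 mm off;
    # the directed distance multiset is 99 zeros and one 10
    base = np.array([[20.0 * i, 0.0, 0.0] for i in range(99)])
    dst = SurfacePointSet(points=base, label="dst")
    src = SurfacePointSet(points=np.vstack([base, [[0.0, 10.0, 0.0]]]), label="src")
    assert compute_hd(src, dst) == pytest.approx(10.0)
    assert compute_hd95(src, dst) == pytest.approx(0.0)


def test_hd95_parallel_slabs_offset():
    grid = make_grid(shape=(40, 40, 8))
    a = box_mask(grid, (0, 0, 0), (40, 40, 1))
    b = box_mask(grid, (0, 0, 4), (40, 40, 5))
    hd95 = compute_hd95(extract_surface(a), extract_surface(b))
    assert hd95 == pytest.approx(4.0, abs=1.0)  # within one voxel


def test_hd_hd95_symmetry_and_translation_invariance(rng):
    grid = make_grid(shape=(10, 10, 6), spacing=(1, 1, 2.5))
    a = random_blob_mask(rng, grid, label="a")
    b = random_blob_mask(rng, grid, label="b")
    if a.is_empty or b.is_empty:
        pytest.skip("degenerate draw")
    sa, sb = extract_surface(a), extract_surface(b)
    assert compute_hd95(sa, sb) == pytest.approx(compute_hd95(sb, sa))
    assert compute_hd(sa, sb) == pytest.approx(compute_hd(sb, sa))
    # shift both masks by one voxel in x inside a larger grid
    big = make_grid(shape=(14, 14, 8), spacing=(1, 1, 2.5))
    occ_a = np.zeros(big.shape, dtype=bool); occ_a[:10, :10, :6] = a.occupancy
    occ_b = np.zeros(big.shape, dtype=bool); occ_b[:10, :10, :6] = b.occupancy
    sh_a = np.roll(occ_a, 2, axis=0); sh_b = np.roll(occ_b, 2, axis=0)
    m = lambda occ: mask_from_array(occ, big)
    assert compute_hd95(
        extract_surface(m(sh_a)), extract_surface(m(sh_b))
    ) == pytest.approx(compute_hd95(extract_surface(m(occ_a)),
                                    extract_surface(m(occ_b))))


# ---------------------------------------------------------------- sDSC


def test_sdsc_identical_is_one_at_any_tau(unit_grid):
    surf = extract_surface(box_mask(unit_grid, (2, 2, 1), (8, 8, 5)))
    for tau in (0.0, 1.0, 2.0, 10.0):
        assert compute_sdsc(surf, surf, tau) == 1.0


def test_sdsc_parallel_slabs_thresholds():
    grid = make_grid(shape=(40, 40, 8))
    a = box_mask(grid, (0, 0, 0), (40, 40, 1))
    near = box_mask(grid, (0, 0, 1), (40, 40, 2))  # 1 mm offset
    far = box_mask(grid, (0, 0, 4), (40, 40, 5))  # faces 3 mm apart
    sa = extract_surface(a)
    assert compute_sdsc(sa, extract_surface(near), 2.0) == pytest.approx(1.0)
    assert compute_sdsc(sa, extract_surface(far), 2.0) == pytest.approx(0.0)


def test_sdsc_monotone_in_tau_and_saturates(rng):
    grid = make_grid(shape=(9, 9, 6), spacing=(1, 1, 2.5))
    a = random_blob_mask(rng, grid, label="a")
    b = random_blob_mask(rng, grid, label="b")
    if a.is_empty or b.is_empty:
        pytest.skip("degenerate draw")
    sa, sb = extract_surface(a), extract_surface(b)
    taus = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
    vals = [compute_sdsc(sa, sb, t) for t in taus]
    assert all(v1 >= v0 - 1e-12 for v0, v1 in zip(vals, vals[1:]))
    assert compute_sdsc(sa, sb, compute_hd(sa, sb)) == 1.0


def test_sdsc_symmetric_in_arguments(rng):
    grid = make_grid(shape=(9, 9, 6))
    a = extract_surface(random_blob_mask(rng, grid, label="a"))
    b = extract_surface(random_blob_mask(rng, grid, label="b"))
    if a.is_empty or b.is_empty:
        pytest.skip("degenerate draw")
    assert compute_sdsc(a, b, 1.5) == pytest.approx(compute_sdsc(b, a, 1.5))


# ---------------------------------------------------------------- report


def test_geometric_report_identity(unit_grid):
    m = box_mask(unit_grid, (2, 2, 1), (8, 8, 5), label="CTV-T", role="CTV-T")
    rep = geometric_report(m, m)
    assert rep.dsc == 1.0 and rep.hd95_mm == 0.0
    assert all(v == 1.0 for v in rep.sdsc.values())
    assert rep.subset == "tumor"
    assert rep.agreement_band == "almost perfect"
    assert not rep.new_structure


def test_geometric_report_flags_missing_structure(unit_grid):
    ro = box_mask(unit_grid, (2, 2, 1), (8, 8, 5), label="GTVn1", role="GTVn")
    gone = mask_from_array(np.zeros(unit_grid.shape), unit_grid,
                           label="GTVn1", role="GTVn")
    rep = geometric_report(ro, gone)
    assert rep.dsc == 0.0
    assert math.isnan(rep.hd95_mm)
    assert all(math.isnan(v) for v in rep.sdsc.values())
    assert rep.new_structure and not rep.evaluable
    assert rep.subset == "node"


def test_geometric_report_shift_matches_direct_metric_calls(unit_grid):
    a = box_mask(unit_grid, (2, 2, 1), (7, 7, 4), label="GTVp", role="GTVp")
    shifted = np.roll(a.occupancy, 2, axis=0)  # 2 mm uniform shift
    b = mask_from_array(shifted, unit_grid, label="GTVp", role="GTVp")
    rep = geometric_report(a, b, taus=(0.0, 2.0))
    sa, sb = extract_surface(a), extract_surface(b)
    assert rep.dsc == pytest.approx(compute_dsc(a, b))
    assert rep.hd95_mm == pytest.approx(compute_hd95(sa, sb))
    assert rep.sdsc[2.0] == pytest.approx(compute_sdsc(sa, sb, 2.0))
    # oracle recomputation of sdsc_2mm from brute-force distances
    d_ab = pairwise_min_distances_bruteforce(sa, sb)
    d_ba = pairwise_min_distances_bruteforce(sb, sa)
    expected = ((d_ab <= 2.0).sum() + (d_ba <= 2.0).sum()) / (len(sa) + len(sb))
    assert rep.sdsc[2.0] == pytest.approx(expected)
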