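"""Phantom generator: determinism, geometry, deformation and dose properties."""
import math
from dataclasses import replace

import numpy as np
import pytest

from dirqa.dose_metrics import dd_pass_rates, dvh_summary, sample_dose
from dirqa.errors import GeometryError, ValidationError
from dirqa.geometry_metrics import compute_dsc, extract_surface, compute_hd95
from dirqa.synthetic_phantom import (
    DeformationBump,
    PhantomParams,
    deform_anatomy,
    emulate_dir_propagation,
    invert_displacement,
    make_case,
    make_cohort,
    make_dose,
    make_reference_structures,
    perturb_dose,
    smooth_scalar_field,
    smooth_vector_field,
    warp_mask,
)

SMALL = PhantomParams(grid_shape=(40, 40, 20), grid_spacing=(2.0, 2.0, 2.5),
                      n_nodes=1, seed=5)

IDENTITY = replace(
    SMALL,
    anat_translation_mm=(0.0, 0.0, 0.0),
    anat_bump_amplitude_mm=0.0,
    dir_shift_mm=(0.0, 0.0, 0.0),
    dir_error_amplitude_mm=0.0,
    plan_noise_amplitude=0.0,
)


# ------------------------------------------------------------- structures


def test_reference_sphere_volume_matches_analytic():
    p = replace(SMALL, gtvp_radii_mm=(10.0, 10.0, 10.0))
    structs = make_reference_structures(p)
    analytic = 4.0 / 3.0 * math.pi * 10.0**3 / 1000.0  # cm^3
    assert structs["GTVp"].volume_cc == pytest.approx(analytic, rel=0.03)


def test_margins_are_nested():
    structs = make_reference_structures(SMALL)
    for gtv, ctv, ptv in (("GTVp", "CTV-T", "PTV-T"), ("GTVn1", "CTV-N1", "PTV-N1")):
        assert np.all(structs[ctv].occupancy | ~structs[gtv].occupancy)
        assert np.all(structs[ptv].occupancy | ~structs[ctv].occupancy)


def test_reference_structures_deterministic():
    a = make_reference_structures(SMALL, np.random.default_rng(3))
    b = make_reference_structures(SMALL, np.random.default_rng(3))
    assert set(a) == set(b)
    for label in a:
        assert np.array_equal(a[label].occupancy, b[label].occupancy)


def test_oversized_primitive_rejected():
    with pytest.raises(ValidationError):
        make_reference_structures(replace(SMALL, gtvp_radii_mm=(60, 60, 60)))


# ------------------------------------------------------------- deformation


def test_zero_amplitude_deformation_is_identity():
    structs = make_reference_structures(IDENTITY)
    warped, field, changes = deform_anatomy(
        structs, IDENTITY, np.random.default_rng(0)
    )
    assert np.all(field == 0.0)
    for label, m in warped.items():
        assert np.array_equal(m.occupancy, structs[label].occupancy)
    assert all(c == 0.0 for c in changes.values())


def test_pure_translation_preserves_volume_and_shifts_centroid():
    structs = make_reference_structures(SMALL)
    gtv = structs["GTVp"]
    field = np.zeros((3,) + gtv.grid.shape)
    field[0] = 2.0  # uniform +2 mm along x
    warped = warp_mask(gtv, field)
    vol_change = abs(warped.volume_cc - gtv.volume_cc) / gtv.volume_cc
    assert vol_change < 0.02
    shift = warped.centroid_mm() - gtv.centroid_mm()
    assert shift[0] == pytest.approx(2.0, abs=max(gtv.grid.spacing) / 2)
    assert abs(shift[1]) < 0.5 and abs(shift[2]) < 0.5


def test_radial_bump_growth_is_monotone_in_amplitude():
    structs = make_reference_structures(SMALL)
    gtv = structs["GTVp"]
    center = tuple(gtv.centroid_mm())
    volumes = []
    for amp in (0.3, 0.8, 1.5):
        bump = DeformationBump(center_mm=center, width_mm=15.0, amplitude_mm=amp)
        warped, _, changes = deform_anatomy(
            {"GTVp": gtv}, SMALL, np.random.default_rng(0), bumps=[bump]
        )
        assert changes["GTVp"] > 0  # expansion grows the structure
        volumes.append(warped["GTVp"].volume_cc)
    assert volumes[0] < volumes[1] < volumes[2]


def test_excessive_displacement_raises():
    structs = make_reference_structures(SMALL)
    field = np.zeros((3,) + SMALL.grid.shape)
    field[0] = 60.0
    with pytest.raises(GeometryError, match="outside the grid"):
        warp_mask(structs["GTVp"], field)


def test_inverse_displacement_recovers_mask():
    structs = make_reference_structures(SMALL)
    gtv = structs["GTVp"]
    rng = np.random.default_rng(8)
    field = smooth_vector_field(gtv.grid, 15.0, 3.0, rng)
    warped = warp_mask(gtv, field)
    recovered = warp_mask(warped, invert_displacement(field, gtv.grid))
    assert compute_dsc(gtv, recovered) > compute_dsc(gtv, warped)


# ------------------------------------------------------------- DIR emulation


def test_zero_dir_error_gives_perfect_metrics():
    structs = make_reference_structures(IDENTITY)
    ro, _, _ = deform_anatomy(structs, IDENTITY, np.random.default_rng(1))
    dir_set, field, dropped = emulate_dir_propagation(
        ro, IDENTITY, np.random.default_rng(2)
    )
    assert dropped is None and np.all(field == 0.0)
    for label in ro:
        assert compute_dsc(ro[label], dir_set[label]) == 1.0
        assert compute_hd95(
            extract_surface(ro[label]), extract_surface(dir_set[label])
        ) == 0.0


def test_drop_structure_scenario_empties_one_nodal_chain():
    p = replace(SMALL, drop_structure=True, n_nodes=2)
    structs = make_reference_structures(p)
    ro, _, _ = deform_anatomy(structs, p, np.random.default_rng(1))
    dir_set, _, dropped = emulate_dir_propagation(ro, p, np.random.default_rng(2))
    assert dropped == "GTVn2"
    assert dir_set["GTVn2"].is_empty and dir_set["CTV-N2"].is_empty
    assert not dir_set["GTVn1"].is_empty
    assert compute_dsc(ro["GTVn2"], dir_set["GTVn2"]) == 0.0


# ------------------------------------------------------------- dose


def test_dose_covers_each_ptv_at_prescription():
    structs = make_reference_structures(SMALL)
    presc = {"PTV-T": 70.0, "PTV-N1": 54.0}
    dose = make_dose(structs, presc, SMALL.grid, penumbra_sigma_mm=5.0)
    for label, p in presc.items():
        samples, _ = sample_dose(dose, structs[label])
        assert np.all(samples >= p - 1e-9)
        s = dvh_summary(samples, p)
        assert s.v95_fraction == 1.0


def test_dose_zero_penumbra_is_binary():
    structs = make_reference_structures(SMALL)
    dose = make_dose(structs, {"PTV-T": 70.0, "PTV-N1": 54.0}, SMALL.grid,
                     penumbra_sigma_mm=0.0)
    vals = np.unique(dose.values)
    assert set(vals).issubset({0.0, 54.0, 70.0})


def test_dose_falloff_matches_gaussian_of_distance():
    from scipy import ndimage

    structs = make_reference_structures(SMALL)
    ptv = structs["PTV-T"]
    sigma = 5.0
    dose = make_dose({"PTV-T": ptv}, {"PTV-T": 70.0}, SMALL.grid,
                     penumbra_sigma_mm=sigma)
    dist = ndimage.distance_transform_edt(~ptv.occupancy,
                                          sampling=SMALL.grid.spacing)
    outside = ~ptv.occupancy & (dist < 12.0)
    expected = 70.0 * np.exp(-dist[outside] ** 2 / (2 * sigma**2))
    assert np.allclose(dose.values[outside], expected, atol=1e-9)


def test_perturb_dose_zero_amplitude_identity_and_determinism():
    structs = make_reference_structures(SMALL)
    dose = make_dose(structs, {"PTV-T": 70.0, "PTV-N1": 54.0}, SMALL.grid)
    out = perturb_dose(dose, 0.0, 20.0, np.random.default_rng(0))
    assert np.array_equal(out.values, dose.values)
    a = perturb_dose(dose, 0.02, 20.0, np.random.default_rng(42))
    b = perturb_dose(dose, 0.02, 20.0, np.random.default_rng(42))
    assert np.array_equal(a.values, b.values)
    with pytest.raises(ValidationError):
        perturb_dose(dose, 1.0, 20.0, np.random.default_rng(0))


def test_perturb_dose_conserves_total_dose():
    structs = make_reference_structures(SMALL)
    dose = make_dose(structs, {"PTV-T": 70.0, "PTV-N1": 54.0}, SMALL.grid)
    rng = np.random.default_rng(17)
    totals = [
        perturb_dose(dose, 0.05, 20.0, rng).values.sum() for _ in range(10)
    ]
    assert np.mean(totals) == pytest.approx(dose.values.sum(), rel=0.02)


def test_plan_noise_amplitude_orders_dd_pass_rates():
    structs = make_reference_structures(SMALL)
    dose = make_dose(structs, {"PTV-T": 70.0, "PTV-N1": 54.0}, SMALL.grid)
    ptv = structs["PTV-T"]
    dd2_small = []
    dd2_large = []
    for seed in range(10):
        small = perturb_dose(dose, 0.01, 20.0, np.random.default_rng(seed))
        large = perturb_dose(dose, 0.10, 20.0, np.random.default_rng(100 + seed))
        r_small = dd_pass_rates(dose, small, ptv)
        r_large = dd_pass_rates(dose, large, ptv)
        for r in (r_small, r_large):
            assert r.pass_rates_pct[0.02] <= r.pass_rates_pct[0.05] + 1e-12
        dd2_small.append(r_small.pass_rates_pct[0.02])
        dd2_large.append(r_large.pass_rates_pct[0.02])
    assert np.median(dd2_small) > np.median(dd2_large)
    assert np.median(dd2_small) > 90.0


# ------------------------------------------------------------- fields


def test_smooth_fields_are_normalized_and_seeded():
    grid = SMALL.grid
    rng = np.random.default_rng(4)
    f = smooth_scalar_field(grid, 15.0, rng)
    assert abs(f.mean()) < 1e-12
    assert np.abs(f).max() == pytest.approx(1.0)
    v = smooth_vector_field(grid, 15.0, 2.5, np.random.default_rng(4))
    mags = np.sqrt((v**2).sum(axis=0))
    assert mags.max() == pytest.approx(2.5)
    v2 = smooth_vector_field(grid, 15.0, 2.5, np.random.default_rng(4))
    assert np.array_equal(v, v2)


# ------------------------------------------------------------- cohorts


def test_case_and_cohort_determinism():
    a = make_case(replace(SMALL, seed=99))
    b = make_case(replace(SMALL, seed=99))
    for prov in a.bundle.structures:
        for label, m in a.bundle.structures[prov].items():
            assert np.array_equal(
                m.occupancy, b.bundle.structures[prov][label].occupancy
            )
    for plan in a.bundle.doses:
        assert np.array_equal(
            a.bundle.doses[plan].values, b.bundle.doses[plan].values
        )
    c1 = make_cohort(3, template=SMALL, seed=11)
    c2 = make_cohort(3, template=SMALL, seed=11)
    for x, y in zip(c1, c2):
        assert np.array_equal(x.anatomy_field_mm, y.anatomy_field_mm)
        assert np.array_equal(x.dir_field_mm, y.dir_field_mm)


def test_cohort_volume_changes_span_shrinkage_and_growth():
    cases = make_cohort(8, template=SMALL, seed=13)
    changes = [v for c in cases for v in c.volume_changes_pct.values()]
    assert min(changes) < -3.0  # shrinkage present
    assert max(changes) > 3.0  # growth present
    assert all(-40.0 < v < 40.0 for v in changes)


def test_cohort_has_tumor_and_node_subsets():
    from dirqa.structure_ops import build_grouping

    cases = make_cohort(3, template=SMALL, seed=2)
    for case in cases:
        g = build_grouping(case.bundle.structures["RO"].values())
        assert g.tumor and g.node and g.ptv
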