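"""Synthetic phantom: beam geometry, dose response, noise and determinism."""

import numpy as np
import pytest

from gelshot import (
    BeamSpec,
    DomainError,
    DoseModel,
    GeometryError,
    PhantomSpec,
    VOICylinder,
    beam_direction,
    dose_to_hu,
    simulate_phantom,
    voi_stats,
)
from gelshot.phantom import background_field, track_field

from conftest import small_star_spec


# -- beam_direction ---------------------------------------------------------

@pytest.mark.parametrize(
    "gantry,couch,expected",
    [
        (0, 0, (0, -1, 0)),     # gantry 0 fires straight down
        (90, 0, (1, 0, 0)),     # gantry 90 fires along +x
        (180, 0, (0, 1, 0)),
        (90, 90, (0, 0, 1)),    # couch 90 turns the lateral beam along the couch axis
    ],
)
def test_beam_direction_convention(gantry, couch, expected):
    np.testing.assert_allclose(beam_direction(gantry, couch), expected, atol=1e-12)


def test_beam_direction_is_unit_for_arbitrary_angles():
    rng = np.random.default_rng(2)
    for g, c in rng.uniform(-360, 360, size=(50, 2)):
        assert np.linalg.norm(beam_direction(g, c)) == pytest.approx(1.0, abs=1e-12)


# -- dose response ----------------------------------------------------------

def test_dose_response_zero_and_linear_branch():
    model = DoseModel(sensitivity_hu_per_gy=2.0)
    assert dose_to_hu(0.0, model) == 0.0
    # halfway through the linear range: slope * d_lin / 2 = d_lin for s = 2
    assert dose_to_hu(model.d_lin_gy / 2, model) == pytest.approx(model.d_lin_gy)


def test_dose_response_monotone_and_continuous():
    model = DoseModel()
    grid = np.linspace(0.0, 60.0, 6001)
    vals = dose_to_hu(grid, model)
    assert np.all(np.diff(vals) >= -1e-12)  # non-decreasing
    # continuity at the breakpoints
    for d in (model.d_lin_gy, model.d_sat_gy):
        lo, hi = dose_to_hu(d - 1e-9, model), dose_to_hu(d + 1e-9, model)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)
    assert dose_to_hu(59.0, model) == dose_to_hu(41.0, model)  # saturated


def test_negative_dose_rejected():
    with pytest.raises(DomainError):
        dose_to_hu(-1.0)


# -- simulator --------------------------------------------------------------

def test_central_voi_std_matches_noise_preset():
    spec = small_star_spec(beams=[], noise_std_hu=1.555, hardening_amp_hu=0.0)
    bg, _, _ = simulate_phantom(spec)
    voi = VOICylinder(center=(0, 0, 0), diameter_mm=20, length_mm=20)
    _, std, n = voi_stats(bg[0], voi)
    assert n >= 1000
    assert std == pytest.approx(1.555, rel=0.15)


def test_track_profile_fwhm_matches_mlc_gap():
    gap = 2.0
    spec = small_star_spec(
        beams=[BeamSpec(0.0, gap_mm=gap)], noise_std_hu=0.0, seed=5
    )
    _, irr, truth = simulate_phantom(spec)
    tracks = track_field(spec, truth.true_lines)
    # profile across the vertical track at the target plane, fine sampling
    x = np.linspace(-6, 6, 1201)
    j = spec.shape[1] // 2
    prof = np.interp(
        x, np.arange(spec.shape[2]) * 1.0 + spec.origin[0],
        tracks[spec.shape[0] // 2, j, :],
    )
    half = prof.max() / 2.0
    above = x[prof >= half]
    fwhm = above.max() - above.min()
    assert fwhm == pytest.approx(gap, abs=2 * spec.penumbra_sigma_mm)


def test_noiseless_background_subtraction_leaves_exact_tracks():
    spec = small_star_spec(noise_std_hu=0.0)
    bg, irr, truth = simulate_phantom(spec)
    residual = irr[0].voxels - bg[0].voxels
    np.testing.assert_allclose(residual, track_field(spec, truth.true_lines), atol=1e-9)


def test_same_seed_is_bitwise_identical():
    a = simulate_phantom(small_star_spec(seed=42))
    b = simulate_phantom(small_star_spec(seed=42))
    for sa, sb in zip(a[:2], b[:2]):
        for va, vb in zip(sa.volumes, sb.volumes):
            np.testing.assert_array_equal(va.voxels, vb.voxels)


def test_ground_truth_scatter_semantics():
    tgt = np.array([1.0, -2.0, 0.0])
    spec0 = small_star_spec(target_point=tuple(tgt), beam_scatter_mm=0.0)
    _, _, truth0 = simulate_phantom(spec0)
    np.testing.assert_allclose(truth0.true_isocenter, tgt)
    for line in truth0.true_lines:
        assert float(line.distance(tgt)) < 1e-12

    scatter = 0.7
    spec1 = small_star_spec(target_point=tuple(tgt), beam_scatter_mm=scatter, seed=9)
    _, _, truth1 = simulate_phantom(spec1)
    np.testing.assert_allclose(truth1.true_isocenter, tgt)
    dists = [float(line.distance(tgt)) for line in truth1.true_lines]
    assert max(dists) <= scatter + 1e-12
    assert max(dists) > 0


def test_reference_point_is_container_axis_for_nominal_markers():
    spec = small_star_spec(beams=[])
    _, _, truth = simulate_phantom(spec)
    np.testing.assert_allclose(truth.reference_point[:2], [0.0, 0.0], atol=1e-9)
    assert truth.reference_point[2] == pytest.approx(-1.0)


def test_target_outside_volume_is_geometry_error():
    with pytest.raises(GeometryError):
        simulate_phantom(small_star_spec(target_point=(500.0, 0.0, 0.0)))


def test_background_field_has_expected_regions():
    spec = small_star_spec(beams=[], noise_std_hu=0.0, hardening_amp_hu=-20.0)
    field = background_field(spec)
    mid = field[spec.shape[0] // 2]
    c = spec.container
    # air outside, wall ring, gel center with the hardening dip on the axis
    assert mid[0, 0] == -1000.0
    center = mid[spec.shape[1] // 2, spec.shape[2] // 2]
    assert center == pytest.approx(c.gel_hu + spec.hardening_amp_hu, abs=0.5)
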