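"""Isocenter fitting against closed forms and brute-force oracles, and
track/marker detection against simulator ground truth."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gelshot import (
    BeamSpec,
    DegenerateGeometryError,
    DetectionError,
    Line2D,
    Line3D,
    UsageError,
    beam_direction,
    detect_beams_2d,
    detect_beams_3d,
    detect_markers,
    fit_isocenter_2d,
    fit_isocenter_3d,
    simulate_phantom,
    subtract_background,
)
from gelshot.geometry import fiducial_reference_point

from conftest import small_star_spec

SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def _line2d_through(point, angle_deg):
    t = np.deg2rad(angle_deg + 90.0)
    n = np.array([np.cos(t), np.sin(t)])
    return Line2D(a=n[0], b=n[1], c=float(n @ point), angle_deg=angle_deg % 180.0)


def _maxdist_2d(lines):
    normals = np.array([[ln.a, ln.b] for ln in lines])
    cs = np.array([ln.c for ln in lines])
    return lambda x: np.abs(normals @ np.asarray(x) - cs).max()


def _maxdist_3d(lines):
    return lambda x: max(float(ln.distance(x)) for ln in lines)


def _grid_simplex_oracle(maxdist, start, ndim, span=2.0, step=0.05):
    """Coarse grid search followed by a simplex refinement."""
    axes = [np.arange(-span, span + step / 2, step) for _ in range(ndim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1) + np.asarray(start)
    vals = np.array([maxdist(p) for p in pts])
    best = pts[np.argmin(vals)]
    res = minimize(
        maxdist, best, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 5000},
    )
    return res.x, maxdist(res.x)


def _tangent_bundle_2d(rng, center, radius, n_extra=1):
    """Lines tangent to a known circle whose normals surround the center,
    making it the unique min-max optimum."""
    phi = rng.uniform(0, 2 * np.pi)
    angles = phi + np.deg2rad([0.0, 120.0, 240.0])
    angles = np.concatenate([angles, rng.uniform(0, 2 * np.pi, size=n_extra)])
    lines = []
    for a in angles:
        n = np.array([np.cos(a), np.sin(a)])
        lines.append(Line2D(a=n[0], b=n[1], c=float(n @ center + radius)))
    return lines


def _tangent_bundle_3d(rng, center, radius):
    """Lines tangent to a known sphere; normals form a random tetrahedron,
    whose hull contains the origin, so the center is the unique optimum."""
    tet = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    # random rotation via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    lines = []
    for n in tet @ q.T:
        d = np.cross(n, rng.normal(size=3))
        d /= np.linalg.norm(d)
        lines.append(Line3D(point=np.asarray(center) + radius * n, direction=d))
    return lines


# ---------------------------------------------------------------------------
# 2D fit
# ---------------------------------------------------------------------------

def test_fit2d_concurrent_lines_radius_zero():
    p = np.array([3.0, -2.0])
    lines = [_line2d_through(p, a) for a in (10.0, 75.0, 140.0)]
    res = fit_isocenter_2d(lines)
    np.testing.assert_allclose(res.center, p, atol=1e-9)
    assert res.radius_mm == pytest.approx(0.0, abs=1e-9)


def test_fit2d_incircle_closed_form():
    # x = 0, y = 0, x + y = 2: incircle of the right triangle
    lines = [
        Line2D(a=1, b=0, c=0),
        Line2D(a=0, b=1, c=0),
        Line2D(a=1 / SQRT2, b=1 / SQRT2, c=SQRT2),
    ]
    res = fit_isocenter_2d(lines)
    np.testing.assert_allclose(res.center, [2 - SQRT2, 2 - SQRT2], atol=1e-9)
    assert res.radius_mm == pytest.approx(2 - SQRT2, abs=1e-9)


def test_fit2d_tangent_construction():
    rng = np.random.default_rng(0)
    lines = _tangent_bundle_2d(rng, center=np.array([1.0, 2.0]), radius=0.5, n_extra=1)
    res = fit_isocenter_2d(lines, reference=(0.0, 0.0))
    np.testing.assert_allclose(res.center, [1.0, 2.0], atol=1e-7)
    assert res.radius_mm == pytest.approx(0.5, abs=1e-7)
    assert res.offset_mm == pytest.approx(np.hypot(1.0, 2.0), abs=1e-6)


def test_fit2d_matches_grid_simplex_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        center = rng.uniform(-3, 3, size=2)
        radius = rng.uniform(0.05, 1.5)
        lines = _tangent_bundle_2d(rng, center, radius, n_extra=rng.integers(0, 3))
        res = fit_isocenter_2d(lines)
        _, r_oracle = _grid_simplex_oracle(_maxdist_2d(lines), res.ls_center, 2)
        assert res.radius_mm == pytest.approx(r_oracle, abs=1e-6)
        np.testing.assert_allclose(res.center, center, atol=1e-4)


def test_fit2d_degenerate_and_usage_errors():
    with pytest.raises(UsageError):
        fit_isocenter_2d([Line2D(a=1, b=0, c=0)])
    with pytest.raises(DegenerateGeometryError):
        fit_isocenter_2d([Line2D(a=1, b=0, c=0), Line2D(a=-1, b=0, c=3)])


def test_fit2d_rotation_invariance():
    rng = np.random.default_rng(2)
    lines = _tangent_bundle_2d(rng, np.array([0.7, -0.4]), 0.3, n_extra=2)
    ref = np.array([1.0, 1.0])
    base = fit_isocenter_2d(lines, reference=ref)
    for theta in (30.0, 117.0, 245.0):
        t = np.deg2rad(theta)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        rlines = [
            Line2D(a=float(rot[0] @ [ln.a, ln.b]), b=float(rot[1] @ [ln.a, ln.b]), c=ln.c)
            for ln in lines
        ]
        res = fit_isocenter_2d(rlines, reference=rot @ ref)
        np.testing.assert_allclose(res.center, rot @ base.center, atol=1e-9)
        assert res.radius_mm == pytest.approx(base.radius_mm, abs=1e-9)
        assert res.offset_mm == pytest.approx(base.offset_mm, abs=1e-9)


# ---------------------------------------------------------------------------
# 3D fit
# ---------------------------------------------------------------------------

def test_fit3d_concurrent_lines_radius_zero():
    p = np.array([0.3, -1.2, 2.0])
    dirs = [beam_direction(g, c) for g, c in ((0, 0), (90, 0), (150, 45), (300, 300))]
    lines = [Line3D(point=p, direction=d) for d in dirs]
    res = fit_isocenter_3d(lines)
    np.testing.assert_allclose(res.center, p, atol=1e-6)
    assert res.radius_mm == pytest.approx(0.0, abs=1e-6)


def test_fit3d_two_skew_lines_hand_solution():
    lines = [
        Line3D(point=(0, 0, 0), direction=(1, 0, 0)),
        Line3D(point=(0, 1, 0), direction=(0, 0, 1)),
    ]
    res = fit_isocenter_3d(lines)
    np.testing.assert_allclose(res.center, [0.0, 0.5, 0.0], atol=1e-6)
    assert res.radius_mm == pytest.approx(0.5, abs=1e-6)
    np.testing.assert_allclose(res.ls_center, res.center, atol=1e-9)


def test_fit3d_tangent_construction_many_bundles():
    rng = np.random.default_rng(3)
    for _ in range(25):
        center = rng.uniform(-2, 2, size=3)
        radius = rng.uniform(0.05, 1.0)
        lines = _tangent_bundle_3d(rng, center, radius)
        res = fit_isocenter_3d(lines)
        np.testing.assert_allclose(res.center, center, atol=1e-4)
        assert res.radius_mm == pytest.approx(radius, abs=1e-4)
        # min-max radius never exceeds the worst distance at the LS center
        assert res.radius_mm <= res.per_beam_distance_mm.max() + 1e-12
        assert res.radius_mm <= _maxdist_3d(lines)(res.ls_center) + 1e-12


def test_fit3d_matches_grid_simplex_oracle():
    rng = np.random.default_rng(4)
    for _ in range(5):
        center = rng.uniform(-1, 1, size=3)
        radius = rng.uniform(0.1, 0.8)
        lines = _tangent_bundle_3d(rng, center, radius)
        res = fit_isocenter_3d(lines)
        _, r_oracle = _grid_simplex_oracle(
            _maxdist_3d(lines), res.ls_center, 3, span=1.0, step=0.1
        )
        assert res.radius_mm == pytest.approx(r_oracle, abs=1e-5)


def test_fit3d_parallel_lines_degenerate():
    lines = [
        Line3D(point=(0, 0, 0), direction=(0, 0, 1)),
        Line3D(point=(1, 0, 0), direction=(0, 0, 1)),
    ]
    with pytest.raises(DegenerateGeometryError):
        fit_isocenter_3d(lines)


# ---------------------------------------------------------------------------
# detection against the simulator
# ---------------------------------------------------------------------------

def _star_slab(spec):
    bg, irr, truth = simulate_phantom(spec)
    sub = subtract_background(irr[0], bg[0])
    z_axis, y_axis, x_axis = sub.axis_coords()
    i0 = int(np.argmin(np.abs(z_axis - 0.0)))
    slab = sub.voxels[max(i0 - 2, 0) : i0 + 3].mean(axis=0)
    return slab, x_axis, y_axis, truth


def _true_line2d(line3d):
    p = line3d.point[:2]
    d = line3d.direction[:2]
    d = d / np.linalg.norm(d)
    n = np.array([-d[1], d[0]])
    return n, float(n @ p)


def test_detect2d_noiseless_star_recovers_ground_truth():
    spec = small_star_spec(noise_std_hu=0.0)
    slab, x, y, truth = _star_slab(spec)
    lines = detect_beams_2d(slab, x, y, n_expected=4, gap_mm=2.0)
    matched = 0
    for tl in truth.true_lines:
        n_true, c_true = _true_line2d(tl)
        ang_true = np.rad2deg(np.arctan2(-n_true[0], n_true[1])) % 180.0
        for ln in lines:
            dang = abs((ln.angle_deg - ang_true + 90.0) % 180.0 - 90.0)
            if dang < 0.2:
                sgn = np.sign(ln.a * n_true[0] + ln.b * n_true[1]) or 1.0
                assert abs(sgn * ln.c - c_true) < 0.05
                matched += 1
                break
    assert matched == 4


def test_detect2d_noisy_star_within_quarter_mm():
    spec = small_star_spec(seed=13)  # default preset noise
    slab, x, y, truth = _star_slab(spec)
    lines = detect_beams_2d(slab, x, y, n_expected=4, gap_mm=2.0)
    res = fit_isocenter_2d(lines)
    err = np.linalg.norm(res.center - truth.true_isocenter[:2])
    assert err < 0.25


def test_detect2d_blank_image_is_detection_error():
    rng = np.random.default_rng(6)
    x = np.arange(64.0) - 32.0
    with pytest.raises(DetectionError):
        detect_beams_2d(rng.normal(0, 1.5, size=(64, 64)), x, x, n_expected=4)


def _beams_3d():
    # the 3D pattern: a 5 x 5 mm field at four gantry/collimator/couch settings
    return [
        BeamSpec(g, c, cc, gap_mm=5.0, field_length_mm=5.0)
        for g, c, cc in ((0, 0, 0), (90, 90, 90), (150, 30, 45), (300, 300, 300))
    ]


def test_detect3d_recovers_axes():
    beams = _beams_3d()
    spec = small_star_spec(beams=beams, noise_std_hu=0.0, shape=(24, 96, 96))
    bg, irr, truth = simulate_phantom(spec)
    sub = subtract_background(irr[0], bg[0])
    dirs = [beam_direction(b.gantry_deg, b.couch_deg) for b in beams]
    lines = detect_beams_3d(sub, dirs, gap_mm=5.0)
    for det, true in zip(lines, truth.true_lines):
        dang = np.rad2deg(
            np.arccos(np.clip(abs(float(det.direction @ true.direction)), 0, 1))
        )
        assert dang < 0.1
        assert float(true.distance(det.point)) < 0.05


def test_detect3d_noisy_within_tolerances():
    from gelshot import average_series

    beams = _beams_3d()
    spec = small_star_spec(beams=beams, seed=17, shape=(24, 96, 96))
    bg, irr, truth = simulate_phantom(spec)
    sub = subtract_background(average_series(irr), average_series(bg))
    dirs = [beam_direction(b.gantry_deg, b.couch_deg) for b in beams]
    lines = detect_beams_3d(sub, dirs, gap_mm=5.0)
    for det, true in zip(lines, truth.true_lines):
        dang = np.rad2deg(
            np.arccos(np.clip(abs(float(det.direction @ true.direction)), 0, 1))
        )
        assert dang < 0.5
        assert float(true.distance(det.point)) < 0.3


def test_detect3d_coincident_directions_usage_error():
    spec = small_star_spec(noise_std_hu=0.0)
    bg, irr, _ = simulate_phantom(spec)
    sub = subtract_background(irr[0], bg[0])
    with pytest.raises(UsageError):
        detect_beams_3d(sub, [np.array([0, -1, 0]), np.array([0, -1.0, 0])])


def test_fitted_radius_grows_with_beam_scatter():
    """The star-shot radius of a scattered bundle increases monotonically
    with the scatter amplitude (Spearman rho > 0.9 over 10 levels x 10
    seeds of simulated beam geometry)."""
    from scipy.stats import spearmanr

    from gelshot.phantom import _scattered_lines

    levels = np.linspace(0.1, 2.0, 10)
    mean_radii = []
    for scatter in levels:
        radii = []
        for seed in range(10):
            spec = small_star_spec(beam_scatter_mm=float(scatter), seed=seed)
            rng = np.random.default_rng(spec.seed)
            lines3d = _scattered_lines(spec, rng)
            lines2d = []
            for ln in lines3d:
                d = ln.direction[:2]
                d = d / np.linalg.norm(d)
                n = np.array([-d[1], d[0]])
                lines2d.append(Line2D(a=n[0], b=n[1], c=float(n @ ln.point[:2])))
            radii.append(fit_isocenter_2d(lines2d).radius_mm)
        mean_radii.append(np.mean(radii))
    rho, _ = spearmanr(levels, mean_radii)
    assert rho > 0.9


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------

def test_reference_point_symmetric_construction():
    r = 40.0
    ref = fiducial_reference_point((0, r, -1), (r, 0, -1), (-r, 0, -1))
    np.testing.assert_allclose(ref, [0.0, 0.0, -1.0], atol=1e-12)


def test_detect_markers_centroids_and_reference():
    spec = small_star_spec(beams=[], seed=8)
    bg, _, truth = simulate_phantom(spec)
    fids = detect_markers(bg[0], (0.0, 90.0, 270.0), search_z=-1.0)
    for angle, true_ctr in zip((0.0, 90.0, 270.0), truth.marker_centers):
        got = fids.markers[angle]
        assert np.linalg.norm(got - true_ctr) < 1.0  # within half the largest voxel
    # reference point sits on the container axis
    assert np.linalg.norm(fids.reference_point[:2] - truth.reference_point[:2]) < 0.5


def test_detect_markers_absent_is_detection_error():
    spec = small_star_spec(beams=[], markers=())
    bg, _, _ = simulate_phantom(spec)
    with pytest.raises(DetectionError):
        detect_markers(bg[0], (0.0, 90.0, 270.0), search_z=-1.0)
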