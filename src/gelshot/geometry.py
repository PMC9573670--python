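"""Beam-track detection and isocenter fitting.

The irradiation isocenter is estimated from the central axes of narrow
beam tracks:

* **2D (star shot)** — the tracks in one transversal plane are lines;
  the isocenter is the center of the smallest circle touching every
  line (the Chebyshev / min-max center), found exactly as a linear
  program: minimize ``r`` subject to ``-r <= a_i x + b_i y - c_i <= r``.
* **3D** — the tracks are skew lines in space; the isocenter is the
  center of the smallest sphere touching every axis, found by convex
  minimization of the largest point-to-line distance seeded at the
  closed-form least-squares intersection point (the solution of
  ``sum_i (I - d_i d_i^T) (x - p_i) = 0``).

Both fits also report the least-squares center, the per-beam distances,
and the offset of the fitted center from a fiducial-derived reference
point, with pass/fail verdicts against the star-shot tolerance
(radius <= 1 mm) and a machine-performance-check style offset
tolerance (<= 0.5 mm).

Track detection works on background-subtracted images: the 2D detector
projects the image over a fine angle grid (a sinogram) and picks the
angles where a track lines up with the projection rays, then refines
each line by intensity-weighted orthogonal regression; the 3D detector
is guided by the planned beam directions and iterates intensity-weighted
principal-axis fits of the voxel cloud near each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateGeometryError,
    DetectionError,
    GeometryError,
    UsageError,
)
from .volume_io import CTVolume

__all__ = [
    "Line2D",
    "Line3D",
    "FiducialSet",
    "IsocenterResult",
    "TG142_RADIUS_TOLERANCE_MM",
    "MPC_OFFSET_TOLERANCE_MM",
    "fiducial_reference_point",
    "detect_beams_2d",
    "detect_beams_3d",
    "detect_markers",
    "fit_isocenter_2d",
    "fit_isocenter_3d",
]

TG142_RADIUS_TOLERANCE_MM = 1.0  # star-shot circle radius tolerance
MPC_OFFSET_TOLERANCE_MM = 0.5  # vendor machine-performance-check threshold


@dataclass(frozen=True)
class Line2D:
    """Line in a transversal plane, Hesse normal form.

    ``a*x + b*y = c`` with ``a**2 + b**2 == 1``; the signed distance of a
    point is ``a*x + b*y - c``.  ``angle_deg`` is the direction of the
    track (mod 180), ``plane_z`` the mm position of the plane.
    """

    a: float
    b: float
    c: float
    plane_z: float = 0.0
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        n = float(np.hypot(self.a, self.b))
        if n == 0:
            raise UsageError("line normal must be non-zero")
        object.__setattr__(self, "a", self.a / n)
        object.__setattr__(self, "b", self.b / n)
        object.__setattr__(self, "c", self.c / n)

    @classmethod
    def from_angle_offset(
        cls, track_angle_deg: float, offset_mm: float, plane_z: float = 0.0
    ) -> "Line2D":
        """Line with track direction ``track_angle_deg`` at signed normal
        offset ``offset_mm`` from the plane origin."""
        t = np.deg2rad(track_angle_deg + 90.0)  # normal angle
        return cls(
            a=float(np.cos(t)),
            b=float(np.sin(t)),
            c=float(offset_mm),
            plane_z=plane_z,
            angle_deg=track_angle_deg % 180.0,
        )

    def signed_distance(self, xy) -> np.ndarray:
        xy = np.asarray(xy, float)
        return xy[..., 0] * self.a + xy[..., 1] * self.b - self.c


@dataclass(frozen=True)
class Line3D:
    """Line in space through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, float).reshape(3)
        d = np.asarray(self.direction, float).reshape(3)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise UsageError("direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    def distance(self, xyz) -> np.ndarray:
        """Perpendicular distance(s) of mm point(s) to the line."""
        r = np.asarray(xyz, float) - self.point
        along = r @ self.direction
        perp = r - np.multiply.outer(along, self.direction)
        return np.linalg.norm(perp, axis=-1)


@dataclass
class FiducialSet:
    """Three surface fiducials and the reference point they define.

    ``markers`` maps the nominal angular position (deg) to the detected
    mm center.  The reference point is the foot of the perpendicular
    from the first-listed marker onto the line through the other two —
    with the standard 0/90/270 degree layout this is the intersection of
    the 90-270 chord with the perpendicular through the 0 degree marker,
    and it coincides with the container axis for a perfectly placed set.
    """

    markers: dict[float, np.ndarray]
    reference_point: np.ndarray
    plane_z: float


def fiducial_reference_point(m_top, m_a, m_b) -> np.ndarray:
    """Foot of the perpendicular from ``m_top`` onto the line (m_a, m_b)."""
    m_top = np.asarray(m_top, float)
    m_a = np.asarray(m_a, float)
    m_b = np.asarray(m_b, float)
    u = m_b - m_a
    n = float(np.linalg.norm(u))
    if n == 0:
        raise GeometryError("chord markers coincide; fiducials are collinear")
    u = u / n
    return m_a + float((m_top - m_a) @ u) * u


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class IsocenterResult:
    """Fitted isocenter with per-beam distances, offset and verdicts."""

    center: np.ndarray
    radius_mm: float
    ls_center: np.ndarray
    per_beam_distance_mm: np.ndarray
    offset_vector: np.ndarray | None = None
    offset_mm: float | None = None
    offset_inplane_mm: float | None = None
    tg142_tolerance_mm: float = TG142_RADIUS_TOLERANCE_MM
    mpc_tolerance_mm: float = MPC_OFFSET_TOLERANCE_MM
    verdicts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.ls_center = np.asarray(self.ls_center, float)
        self.per_beam_distance_mm = np.asarray(self.per_beam_distance_mm, float)
        if self.offset_vector is not None and self.offset_inplane_mm is None:
            # transversal (x, y) component; whether a QA report's "offset"
            # means the 3D or the in-plane distance varies, so keep both
            self.offset_inplane_mm = float(
                np.linalg.norm(np.asarray(self.offset_vector, float)[:2])
            )
        self.verdicts = {
            "tg142": bool(self.radius_mm <= self.tg142_tolerance_mm),
            "mpc_style": (
                None if self.offset_mm is None
                else bool(self.offset_mm <= self.mpc_tolerance_mm)
            ),
        }

    @property
    def passed(self) -> bool:
        return self.verdicts["tg142"] and self.verdicts["mpc_style"] is not False

    def to_dict(self) -> dict:
        return {
            "center_mm": [float(v) for v in self.center],
            "radius_mm": float(self.radius_mm),
            "ls_center_mm": [float(v) for v in self.ls_center],
            "per_beam_distance_mm": [float(v) for v in self.per_beam_distance_mm],
            "offset_vector_mm": (
                None if self.offset_vector is None
                else [float(v) for v in self.offset_vector]
            ),
            "offset_mm": None if self.offset_mm is None else float(self.offset_mm),
            "offset_inplane_mm": (
                None if self.offset_inplane_mm is None else float(self.offset_inplane_mm)
            ),
            "tolerances_mm": {
                "tg142": self.tg142_tolerance_mm,
                "mpc_style": self.mpc_tolerance_mm,
            },
            "verdicts": self.verdicts,
        }


def _offset_fields(center: np.ndarray, reference) -> tuple:
    if reference is None:
        return None, None
    ref = np.asarray(reference, float)[: center.size]
    vec = center - ref
    return vec, float(np.linalg.norm(vec))


# ---------------------------------------------------------------------------
# Isocenter fits
# ---------------------------------------------------------------------------

def fit_isocenter_2d(
    lines: Sequence[Line2D],
    reference=None,
    tg142_tolerance_mm: float = TG142_RADIUS_TOLERANCE_MM,
    mpc_tolerance_mm: float = MPC_OFFSET_TOLERANCE_MM,
) -> IsocenterResult:
    """Smallest circle touching all lines (linear program, exact).

    The optimum of ``min r  s.t.  |a_i x + b_i y - c_i| <= r`` is found
    with the HiGHS solver; the least-squares center (minimizing the sum
    of squared distances) is reported alongside.
    """
    if len(lines) < 2:
        raise UsageError("need at least 2 lines")
    normals = np.array([[ln.a, ln.b] for ln in lines])
    cs = np.array([ln.c for ln in lines])
    # parallel bundle: all normals equal up to sign
    if np.all(np.abs(normals @ normals[0]) > 1.0 - 1e-12):
        raise DegenerateGeometryError("all lines are parallel")

    a_ub = np.block(
        [[normals, -np.ones((len(lines), 1))], [-normals, -np.ones((len(lines), 1))]]
    )
    b_ub = np.concatenate([cs, -cs])
    res = optimize.linprog(
        c=[0.0, 0.0, 1.0],
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(None, None), (None, None), (0.0, None)],
        method="highs",
    )
    if not res.success:  # pragma: no cover - guarded by the parallel check
        raise DegenerateGeometryError(f"LP failed: {res.message}")
    center = res.x[:2]

    n_mat = normals.T @ normals
    ls_center = np.linalg.solve(n_mat, normals.T @ cs)

    dists = np.abs(normals @ center - cs)
    vec, off = _offset_fields(center, reference)
    return IsocenterResult(
        center=center,
        radius_mm=float(dists.max()),
        ls_center=ls_center,
        per_beam_distance_mm=dists,
        offset_vector=vec,
        offset_mm=off,
        tg142_tolerance_mm=tg142_tolerance_mm,
        mpc_tolerance_mm=mpc_tolerance_mm,
    )


def least_squares_intersection(lines: Sequence[Line3D]) -> np.ndarray:
    """Closed-form point minimizing the sum of squared line distances.

    Solves the normal equations ``sum_i (I - d_i d_i^T) (x - p_i) = 0``.
    Raises :class:`DegenerateGeometryError` when the bundle is parallel
    (rank-deficient normal matrix).
    """
    m = np.zeros((3, 3))
    rhs = np.zeros(3)
    for ln in lines:
        proj = np.eye(3) - np.outer(ln.direction, ln.direction)
        m += proj
        rhs += proj @ ln.point
    w = np.linalg.eigvalsh(m)
    if w[0] < 1e-9 * max(w[-1], 1.0):
        raise DegenerateGeometryError("all lines are parallel; no unique center")
    return np.linalg.solve(m, rhs)


def fit_isocenter_3d(
    lines: Sequence[Line3D],
    reference=None,
    tg142_tolerance_mm: float = TG142_RADIUS_TOLERANCE_MM,
    mpc_tolerance_mm: float = MPC_OFFSET_TOLERANCE_MM,
) -> IsocenterResult:
    """Smallest sphere touching all beam axes (min-max center).

    Convex minimization of the largest point-to-line distance, seeded at
    the least-squares intersection point: an epigraph SLSQP solve
    followed by a Nelder-Mead polish of ``max_i dist_i`` (the best of
    the two is kept, well within 1e-6 mm of optimal for non-degenerate
    bundles).
    """
    if len(lines) < 2:
        raise UsageError("need at least 2 lines")
    ls_center = least_squares_intersection(lines)

    def maxdist(x: np.ndarray) -> float:
        return float(max(ln.distance(x) for ln in lines))

    r0 = maxdist(ls_center)
    candidates = [(r0, ls_center)]

    if r0 > 0:
        cons = [
            {
                "type": "ineq",
                "fun": (lambda u, ln=ln: u[3] - float(ln.distance(u[:3]))),
            }
            for ln in lines
        ]
        res = optimize.minimize(
            lambda u: u[3],
            x0=np.append(ls_center, r0 * (1 + 1e-6) + 1e-9),
            constraints=cons,
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        if res.success:
            candidates.append((maxdist(res.x[:3]), res.x[:3]))
        nm = optimize.minimize(
            maxdist,
            x0=min(candidates, key=lambda t: t[0])[1],
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
        )
        candidates.append((maxdist(nm.x), nm.x))

    radius, center = min(candidates, key=lambda t: t[0])
    dists = np.array([float(ln.distance(center)) for ln in lines])
    vec, off = _offset_fields(center, reference)
    return IsocenterResult(
        center=center,
        radius_mm=float(radius),
        ls_center=ls_center,
        per_beam_distance_mm=dists,
        offset_vector=vec,
        offset_mm=off,
        tg142_tolerance_mm=tg142_tolerance_mm,
        mpc_tolerance_mm=mpc_tolerance_mm,
    )


# ---------------------------------------------------------------------------
# 2D track detection (star shot)
# ---------------------------------------------------------------------------

def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_beams_2d(
    image: np.ndarray,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    n_expected: int,
    angle_hints: Sequence[float] | None = None,
    gap_mm: float = 2.0,
    plane_z: float = 0.0,
    angle_step_deg: float = 0.25,
    threshold_sigma: float = 5.0,
) -> list[Line2D]:
    """Detect ``n_expected`` beam-track lines in a star-shot plane.

    ``image`` is a background-subtracted transversal slice (or thin-slab
    mean); ``x_mm``/``y_mm`` give the mm positions of its columns/rows.
    The angle of each track is found from a weighted sinogram sampled
    every ``angle_step_deg`` (projecting parallel to a track gives the
    sharpest, tallest peak); each line is then refined by
    intensity-weighted orthogonal regression over a ribbon of half-width
    ``3 * gap_mm``, excluding the crossing region near the image
    centroid.  Angle ties are broken by peak prominence, then by the
    smaller angle.
    """
    image = np.asarray(image, float)
    sigma = _robust_sigma(image)
    floor = max(threshold_sigma * sigma, 1e-12)
    mask = image > floor
    if mask.sum() < 10:
        raise DetectionError(f"found 0 of {n_expected} tracks (no pixels above noise)")

    xx, yy = np.meshgrid(np.asarray(x_mm, float), np.asarray(y_mm, float))
    px = xx[mask]
    py = yy[mask]
    w = image[mask]
    step = float(min(np.diff(x_mm).min(), np.diff(y_mm).min()))

    if angle_hints is not None:
        if len(angle_hints) != n_expected:
            raise UsageError("angle_hints must have n_expected entries")
        normal_angles = [np.deg2rad(a + 90.0) for a in angle_hints]
    else:
        normal_angles = _sinogram_angles(
            px, py, w, n_expected, angle_step_deg, step
        )

    coarse_center = np.array([np.average(px, weights=w), np.average(py, weights=w)])
    r_excl = max(8.0, 3.0 * gap_mm)
    d_center = np.hypot(px - coarse_center[0], py - coarse_center[1])

    lines = []
    for theta in normal_angles:
        nvec = np.array([np.cos(theta), np.sin(theta)])
        s = px * nvec[0] + py * nvec[1]
        # initial offset: histogram peak of the projection
        bins = np.arange(s.min() - step, s.max() + 2 * step, max(step / 2, 1e-3))
        hist, edges = np.histogram(s, bins=bins, weights=w)
        c = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        for it in range(3):
            # wide ribbon first, then tight to shut out neighbouring tracks
            half_ribbon = 3.0 * gap_mm if it == 0 else 1.5 * gap_mm
            ribbon = np.abs(s - c) <= half_ribbon
            far = ribbon & (d_center > r_excl)
            sel = far if far.sum() >= 10 else ribbon
            if sel.sum() < 3:
                raise DetectionError("ribbon around a detected angle is empty")
            pts = np.stack([px[sel], py[sel]], axis=1)
            wsel = w[sel]
            mu = np.average(pts, axis=0, weights=wsel)
            dp = pts - mu
            cov = (dp * wsel[:, None]).T @ dp / wsel.sum()
            evals, evecs = np.linalg.eigh(cov)
            u = evecs[:, np.argmax(evals)]  # track direction
            nvec = np.array([-u[1], u[0]])
            theta = float(np.arctan2(nvec[1], nvec[0]))
            c = float(mu @ nvec)
            s = px * nvec[0] + py * nvec[1]
        track_angle = (np.rad2deg(theta) - 90.0) % 180.0
        lines.append(
            Line2D(
                a=float(nvec[0]), b=float(nvec[1]), c=float(c),
                plane_z=plane_z, angle_deg=float(track_angle),
            )
        )
    return lines


def _sinogram_angles(
    px: np.ndarray,
    py: np.ndarray,
    w: np.ndarray,
    n_expected: int,
    angle_step_deg: float,
    bin_mm: float,
) -> list[float]:
    """Normal angles (rad) of the ``n_expected`` sharpest projection peaks."""
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import find_peaks

    thetas = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    metric = np.empty(len(thetas))
    smax = float(np.hypot(px, py).max()) + 2 * bin_mm
    bins = np.arange(-smax, smax + bin_mm, max(bin_mm / 2.0, 1e-3))
    for i, t in enumerate(thetas):
        s = px * np.cos(t) + py * np.sin(t)
        hist, _ = np.histogram(s, bins=bins, weights=w)
        metric[i] = hist.max()
    metric = uniform_filter1d(metric, size=3, mode="wrap")

    floor = np.median(metric) + 6.0 * _robust_sigma(metric)
    pad = len(metric) // 4
    wrapped = np.concatenate([metric[-pad:], metric, metric[:pad]])
    peaks, props = find_peaks(wrapped, height=floor, prominence=0.0)
    peaks -= pad
    keep = (peaks >= 0) & (peaks < len(metric))
    peaks, prom = peaks[keep], props["prominences"][keep]
    # deduplicate angles closer than 2 degrees (keep the more prominent)
    order = sorted(range(len(peaks)), key=lambda i: (-prom[i], peaks[i]))
    chosen: list[int] = []
    min_sep = max(int(round(2.0 / angle_step_deg)), 1)
    for i in order:
        if all(
            min(abs(peaks[i] - j), len(metric) - abs(peaks[i] - j)) >= min_sep
            for j in (peaks[k] for k in chosen)
        ):
            chosen.append(i)
    if len(chosen) < n_expected:
        raise DetectionError(
            f"found {len(chosen)} of {n_expected} track angles above the noise floor"
        )
    chosen = chosen[:n_expected]
    return [float(thetas[peaks[i]]) for i in chosen]


# ---------------------------------------------------------------------------
# 3D track detection
# ---------------------------------------------------------------------------

def detect_beams_3d(
    volume: CTVolume,
    planned_directions: Sequence[np.ndarray],
    gap_mm: float = 2.0,
    threshold_sigma: float = 5.0,
    min_voxels: int = 50,
    max_iter: int = 10,
) -> list[Line3D]:
    """Fit one 3D line per planned beam direction (guided detection).

    Candidate voxels above ``threshold_sigma`` times the robust noise Std
    are assigned to the nearest planned axis through the coarse centroid;
    each axis is then the intensity-weighted first principal axis of its
    voxel cloud, iterating the selection within ``2 * gap_mm`` of the
    current line until the axis moves less than 0.01 mm / 0.01 degrees.
    """
    dirs = [np.asarray(d, float) / np.linalg.norm(d) for d in planned_directions]
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            if abs(float(dirs[i] @ dirs[j])) > 1.0 - 1e-9:
                raise UsageError(f"planned directions {i} and {j} coincide")

    v = volume.voxels
    sigma = _robust_sigma(v)
    mask = v > max(threshold_sigma * sigma, 1e-12)
    if not mask.any():
        raise DetectionError("no voxels above the noise floor")
    idx = np.argwhere(mask)
    pts = volume.index_to_mm(idx[:, 0], idx[:, 1], idx[:, 2])
    w = v[mask]

    centroid = np.average(pts, axis=0, weights=w)
    r_excl = max(5.0, 3.0 * gap_mm)
    d_centroid = np.linalg.norm(pts - centroid, axis=1)

    # initial assignment to the nearest planned axis through the centroid
    dist_to_planned = np.stack(
        [Line3D(point=centroid, direction=d).distance(pts) for d in dirs], axis=1
    )
    assign = np.argmin(dist_to_planned, axis=1)

    lines: list[Line3D] = []
    for b, d_plan in enumerate(dirs):
        sel = assign == b
        if sel.sum() < min_voxels:
            raise DetectionError(
                f"beam {b}: only {int(sel.sum())} candidate voxels (need {min_voxels})"
            )
        line = Line3D(point=centroid, direction=d_plan)
        for _ in range(max_iter):
            near = sel & (line.distance(pts) <= 2.0 * gap_mm)
            if near.sum() < min_voxels:
                raise DetectionError(
                    f"beam {b}: only {int(near.sum())} voxels near the axis"
                )
            # trim the rod ends: oblique clipping at the gel or volume
            # boundary shears the cloud and would bias the principal axis
            along_all = (pts[near] - centroid) @ line.direction
            trim = 0.12 * (along_all.max() - along_all.min())
            lo, hi = along_all.min() + trim, along_all.max() - trim
            along_full = (pts - centroid) @ line.direction
            trimmed = near & (along_full >= lo) & (along_full <= hi)
            fit_sel = trimmed & (d_centroid > r_excl)
            if fit_sel.sum() < min_voxels:
                fit_sel = trimmed
            if fit_sel.sum() < min_voxels:
                fit_sel = near
            p = pts[fit_sel]
            ww = w[fit_sel]
            mu = np.average(p, axis=0, weights=ww)
            dp = p - mu
            cov = (dp * ww[:, None]).T @ dp / ww.sum()
            evals, evecs = np.linalg.eigh(cov)
            d_new = evecs[:, np.argmax(evals)]
            if float(d_new @ line.direction) < 0:
                d_new = -d_new
            new_line = Line3D(point=mu, direction=d_new)
            shift = float(new_line.distance(line.point))
            dang = np.rad2deg(
                np.arccos(np.clip(abs(float(d_new @ line.direction)), 0.0, 1.0))
            )
            line = new_line
            if shift < 0.01 and dang < 0.01:
                break
        # anchor the reported point at the foot of the centroid for stability
        foot = line.point + float((centroid - line.point) @ line.direction) * line.direction
        lines.append(Line3D(point=foot, direction=line.direction))
    return lines


# ---------------------------------------------------------------------------
# Fiducial markers
# ---------------------------------------------------------------------------

def detect_markers(
    volume: CTVolume,
    expected_angles: Sequence[float] = (0.0, 90.0, 270.0),
    search_z: float = -1.0,
    z_window_mm: float = 5.0,
    angular_window_deg: float = 20.0,
) -> FiducialSet:
    """Locate bright surface fiducials near ``search_z`` and build the
    reference point.

    Works on a raw (not background-subtracted) volume: markers are small
    dots far brighter than the container wall.  Each expected angle
    (measured from vertical +y, clockwise toward +x, about the container
    axis) gets the intensity-weighted centroid of the bright voxels in
    its angular window on the rim.
    """
    if len(expected_angles) != 3:
        raise UsageError("exactly three expected marker angles are required")
    z_axis, y_axis, x_axis = volume.axis_coords()
    slab = np.abs(z_axis - search_z) <= z_window_mm
    if not slab.any():
        raise GeometryError("search_z slab lies outside the volume")
    sub = volume.voxels[slab]
    zz = z_axis[slab]

    body = sub > -500.0  # non-air
    if not body.any():
        raise DetectionError("no container found in the marker slab")
    xx, yy = np.meshgrid(x_axis, y_axis)
    cx = float(np.mean(np.broadcast_to(xx, sub.shape)[body]))
    cy = float(np.mean(np.broadcast_to(yy, sub.shape)[body]))

    body_vals = sub[body]
    med = float(np.median(body_vals))
    p99 = float(np.percentile(body_vals, 99))
    peak = float(sub.max())
    if peak < p99 + 50.0:  # nothing stands out beyond the container wall
        raise DetectionError("no marker-bright voxels in the slab")
    thr = p99 + 0.5 * (peak - p99)
    bright = sub > thr

    kz, jy, ix = np.nonzero(bright)
    mx = x_axis[ix]
    my = y_axis[jy]
    mz = zz[kz]
    vals = sub[kz, jy, ix] - med
    ang = np.rad2deg(np.arctan2(mx - cx, my - cy)) % 360.0

    markers: dict[float, np.ndarray] = {}
    for a in expected_angles:
        delta = np.abs((ang - a + 180.0) % 360.0 - 180.0)
        sel = delta <= angular_window_deg
        if not sel.any():
            raise DetectionError(f"no marker found near {a} degrees")
        wsel = vals[sel]
        markers[float(a)] = np.array(
            [
                np.average(mx[sel], weights=wsel),
                np.average(my[sel], weights=wsel),
                np.average(mz[sel], weights=wsel),
            ]
        )

    a0, a1, a2 = (float(a) for a in expected_angles)
    ref = fiducial_reference_point(markers[a0], markers[a1], markers[a2])
    return FiducialSet(
        markers=markers,
        reference_point=ref,
        plane_z=float(np.mean([m[2] for m in markers.values()])),
    )
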