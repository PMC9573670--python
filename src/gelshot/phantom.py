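"""Synthetic CBCT phantom of a gel-filled container with known beam tracks.

The simulator emulates what a kV CBCT scan of a polymer-gel dosimeter in a
cylindrical container looks like for isocenter QA:

* a gel cylinder (inner diameter 90 or 80 mm) inside a plastic wall,
  surrounded by air (~ -1000 HU), scanned lying along the couch axis ``z``;
* a radially symmetric beam-hardening bias (parabolic, largest in
  magnitude on the container axis) and optional concentric ring artifacts;
* white Gaussian HU noise whose standard deviation comes from per
  accelerator/algorithm/mode presets measured on clinical systems
  (:data:`NOISE_PRESETS`);
* dose-saturating bright beam tracks: narrow slit fields (MLC gap of a
  few mm, ~10,000 MU) whose polymerization response follows a
  linear-then-saturating dose model, with erf-shaped penumbra;
* three bright surface fiducial markers at the 0/90/270 degree positions
  of the container rim in one transversal plane.

Every simulation returns the exact :class:`~gelshot.geometry.Line3D`
beam axes, marker centers and reference point as :class:`GroundTruth`,
so recovery accuracy of the full analysis chain can be measured.

Beam angles follow the machine convention: gantry 0 fires vertically
down (``-y``), gantry 90 fires along ``+x``, the couch rotates the beam
about the vertical axis, and the collimator only spins the slit about
the beam axis (it never changes the central axis direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .errors import DomainError, GeometryError, UsageError
from .geometry import Line3D, fiducial_reference_point
from .volume_io import CTVolume, SeriesSet

__all__ = [
    "NOISE_PRESETS",
    "noise_std_for",
    "DoseModel",
    "BeamSpec",
    "ContainerSpec",
    "MarkerSpec",
    "PhantomSpec",
    "GroundTruth",
    "beam_direction",
    "collimator_frame",
    "dose_to_hu",
    "simulate_phantom",
    "background_field",
    "track_field",
]

# Measured VOI noise (HU standard deviation, 20 mm diameter x 20 mm VOI) per
# accelerator / reconstruction algorithm / acquisition mode, shipped as the
# default noise levels of the simulator.
NOISE_PRESETS: dict[tuple[str, str, str], float] = {
    ("Halcyon", "CBCT", "Image Gently"): 25.841,
    ("Halcyon", "CBCT", "Image Gently Large"): 16.506,
    ("Halcyon", "CBCT", "Head"): 18.917,
    ("Halcyon", "CBCT", "Head Low Dose"): 24.452,
    ("Halcyon", "CBCT", "Pelvis"): 2.984,
    ("Halcyon", "CBCT", "Pelvis Fast"): 7.403,
    ("Halcyon", "CBCT", "Pelvis Large"): 2.772,
    ("Halcyon", "CBCT", "Pelvis Large Fast"): 4.570,
    ("Halcyon", "iCBCT", "Image Gently"): 9.581,
    ("Halcyon", "iCBCT", "Image Gently Large"): 4.475,
    ("Halcyon", "iCBCT", "Head"): 3.679,
    ("Halcyon", "iCBCT", "Head Low Dose"): 8.465,
    ("Halcyon", "iCBCT", "Pelvis"): 2.129,
    ("Halcyon", "iCBCT", "Pelvis Fast"): 2.703,
    ("Halcyon", "iCBCT", "Pelvis Large"): 1.585,
    ("Halcyon", "iCBCT", "Pelvis Large Fast"): 1.511,
    ("TrueBeam", "CBCT", "Head"): 11.867,
    ("TrueBeam", "CBCT", "Image Gently"): 17.916,
    ("TrueBeam", "CBCT", "Pelvis Large"): 4.986,
    ("TrueBeam", "CBCT", "Pelvis"): 2.743,
    ("TrueBeam", "CBCT", "Short Thorax"): 7.269,
    ("TrueBeam", "CBCT", "Spotlight"): 4.785,
    ("TrueBeam", "CBCT", "Thorax"): 3.746,
    ("TrueBeam", "iCBCT", "Head"): 4.115,
    ("TrueBeam", "iCBCT", "Image Gently"): 6.875,
    ("TrueBeam", "iCBCT", "Pelvis Large"): 3.233,
    ("TrueBeam", "iCBCT", "Pelvis"): 1.555,
}


def noise_std_for(accelerator: str, algorithm: str, mode: str) -> float:
    """Preset HU noise Std for an accelerator/algorithm/mode triple."""
    try:
        return NOISE_PRESETS[(accelerator, algorithm, mode)]
    except KeyError:
        raise UsageError(
            f"no noise preset for {(accelerator, algorithm, mode)!r}"
        ) from None


# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseModel:
    """Linear-then-saturating CT response of the gel.

    The gel responds linearly (``sensitivity_hu_per_gy``) up to
    ``d_lin_gy`` (~18 Gy), bends over (half slope) and saturates at
    ``d_sat_gy`` (~40 Gy); above saturation the response is flat.  The
    default sensitivity is chosen so a fully saturated track peaks near
    +60 HU over the gel background.
    """

    sensitivity_hu_per_gy: float = 60.0 / 29.0
    d_lin_gy: float = 18.0
    d_sat_gy: float = 40.0

    def __post_init__(self) -> None:
        if not self.d_lin_gy < self.d_sat_gy:
            raise UsageError("d_lin_gy must be < d_sat_gy")
        if self.sensitivity_hu_per_gy < 0:
            raise UsageError("sensitivity must be >= 0")

    @property
    def plateau_hu(self) -> float:
        s = self.sensitivity_hu_per_gy
        return s * self.d_lin_gy + 0.5 * s * (self.d_sat_gy - self.d_lin_gy)


def dose_to_hu(dose_gy, dose_model: DoseModel = DoseModel()):
    """HU increment produced by an absorbed dose (piecewise linear, saturating).

    Continuous and non-decreasing: slope ``s`` below ``d_lin``, slope
    ``s/2`` between ``d_lin`` and ``d_sat``, constant above ``d_sat``.
    Negative dose raises :class:`DomainError`.
    """
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be >= 0")
    m = dose_model
    s = m.sensitivity_hu_per_gy
    out = np.where(
        d <= m.d_lin_gy,
        s * d,
        np.where(
            d <= m.d_sat_gy,
            s * m.d_lin_gy + 0.5 * s * (d - m.d_lin_gy),
            m.plateau_hu,
        ),
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamSpec:
    """One slit beam: machine angles, MLC gap and monitor units."""

    gantry_deg: float
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    gap_mm: float = 2.0
    mu: float = 10000.0
    field_length_mm: float = 20.0  # slit length (jaw-limited), mm

    def __post_init__(self) -> None:
        if self.gap_mm < 0:
            raise UsageError("gap_mm must be >= 0")
        if self.mu <= 0:
            raise UsageError("mu must be > 0")


@dataclass(frozen=True)
class ContainerSpec:
    """Gel-filled cylindrical container, axis along z."""

    inner_diameter_mm: float = 90.0
    length_mm: float = 130.0
    wall_thickness_mm: float = 3.0
    wall_hu: float = 120.0
    gel_hu: float = 20.0


@dataclass(frozen=True)
class MarkerSpec:
    """Surface fiducial: angle from vertical (+y, clockwise toward +x)."""

    angle_deg: float
    z_mm: float = -1.0
    radius_mm: float = 1.5
    marker_hu: float = 500.0


def _default_markers() -> tuple[MarkerSpec, ...]:
    return (MarkerSpec(0.0), MarkerSpec(90.0), MarkerSpec(270.0))


@dataclass
class PhantomSpec:
    """Everything needed to simulate one QA session.

    ``target_point`` is the true isocenter of the beam set;
    ``beam_scatter_mm`` is the maximum random perpendicular miss distance
    of each beam axis (0 = perfectly concurrent beams).
    """

    container: ContainerSpec = field(default_factory=ContainerSpec)
    beams: list[BeamSpec] = field(default_factory=list)
    target_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beam_scatter_mm: float = 0.0
    noise_std_hu: float = NOISE_PRESETS[("TrueBeam", "iCBCT", "Pelvis")]
    hardening_amp_hu: float = -20.0
    ring_amp_hu: float = 0.0
    ring_period_mm: float = 8.0
    markers: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    dose_model: DoseModel = field(default_factory=DoseModel)
    gy_per_kmu: float = 10.0  # ~1 Gy per 100 MU at the depth of interest
    penumbra_sigma_mm: float = 0.5
    n_background_series: int = 3
    n_irradiated_series: int = 3
    shape: tuple[int, int, int] = (32, 112, 112)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (sz, sy, sx) mm
    seed: int = 0
    mode_tag: str = "TrueBeam/iCBCT/Pelvis"

    def __post_init__(self) -> None:
        if self.noise_std_hu < 0:
            raise UsageError("noise_std_hu must be >= 0")
        if self.beam_scatter_mm < 0:
            raise UsageError("beam_scatter_mm must be >= 0")

    @property
    def origin(self) -> tuple[float, float, float]:
        """Grid centered on the container axis (x=y=0) and z=0."""
        ni, nj, nk = self.shape
        sz, sy, sx = self.spacing
        return (-(nk - 1) / 2.0 * sx, -(nj - 1) / 2.0 * sy, -(ni - 1) / 2.0 * sz)

    def geometry_volume(self, voxels: np.ndarray) -> CTVolume:
        return CTVolume(
            voxels=voxels,
            spacing=self.spacing,
            origin=self.origin,
            frame_id=f"sim-{self.seed}",
        )


@dataclass
class GroundTruth:
    """Exact simulation geometry for recovery tests."""

    true_lines: list[Line3D]
    true_isocenter: np.ndarray
    marker_centers: list[np.ndarray]
    reference_point: np.ndarray


# ---------------------------------------------------------------------------
# Beam geometry
# ---------------------------------------------------------------------------

def _roty(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def beam_direction(gantry_deg: float, couch_deg: float = 0.0) -> np.ndarray:
    """Unit central-axis direction for gantry/couch angles.

    Gantry 0 fires straight down, ``d(g, c) = Ry(-c) @ (sin g, -cos g, 0)``
    with the couch rotating about the vertical ``y`` axis.  The collimator
    angle does not enter: it only spins the slit about this axis.
    """
    if not (np.isfinite(gantry_deg) and np.isfinite(couch_deg)):
        raise UsageError("angles must be finite")
    g = np.deg2rad(gantry_deg)
    d0 = np.array([np.sin(g), -np.cos(g), 0.0])
    d = _roty(-couch_deg) @ d0
    return d / np.linalg.norm(d)


def collimator_frame(
    direction: np.ndarray, collimator_deg: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """(slit-normal, slit-length) unit vectors perpendicular to the beam.

    At collimator 0 the slit length axis is as close to the container
    axis ``z`` as the beam direction allows, so transversal slices cut
    the slit across its narrow dimension; the collimator angle rotates
    the pair about the beam axis.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    seed = np.array([0.0, 0.0, 1.0])
    if abs(float(d @ seed)) > 0.9:  # beam nearly along the container axis
        seed = np.array([1.0, 0.0, 0.0])
    length_axis = seed - (seed @ d) * d
    length_axis /= np.linalg.norm(length_axis)
    normal_axis = np.cross(d, length_axis)
    if collimator_deg:
        t = np.deg2rad(collimator_deg)
        c, s = np.cos(t), np.sin(t)
        normal_axis, length_axis = (
            c * normal_axis + s * length_axis,
            -s * normal_axis + c * length_axis,
        )
    return normal_axis, length_axis


def _erf_box(t: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Unit-height box of half-width ``half_width`` with erf-smoothed edges."""
    if half_width <= 0:
        return np.zeros_like(t)
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((half_width - t) / s) + erf((half_width + t) / s))


# ---------------------------------------------------------------------------
# Field construction
# ---------------------------------------------------------------------------

def _grids(spec: PhantomSpec):
    ni, nj, nk = spec.shape
    sz, sy, sx = spec.spacing
    x0, y0, z0 = spec.origin
    z = z0 + np.arange(ni) * sz
    y = y0 + np.arange(nj) * sy
    x = x0 + np.arange(nk) * sx
    return z, y, x


def background_field(spec: PhantomSpec) -> np.ndarray:
    """Noiseless background: container + beam hardening + rings + markers."""
    z, y, x = _grids(spec)
    X = x[None, :]
    Y = y[:, None]
    r = np.sqrt(X**2 + Y**2)  # in-plane radius from the container axis

    c = spec.container
    r_in = c.inner_diameter_mm / 2.0
    r_out = r_in + c.wall_thickness_mm

    plane = np.full(r.shape, -1000.0)
    plane[r < r_out] = c.wall_hu
    gel = r < r_in
    plane[gel] = c.gel_hu
    # radial beam-hardening bias, maximal magnitude on the axis
    plane[gel] += spec.hardening_amp_hu * (1.0 - (r[gel] / r_in) ** 2)
    if spec.ring_amp_hu:
        plane[gel] += spec.ring_amp_hu * np.cos(
            2.0 * np.pi * r[gel] / spec.ring_period_mm
        )

    field3d = np.repeat(plane[None, :, :], len(z), axis=0)
    # container has finite length along z (flat gel/air ends ignored beyond it)
    outside_len = np.abs(z) > c.length_mm / 2.0
    field3d[outside_len] = -1000.0

    # surface fiducial markers: bright spheres on the wall
    r_marker_orbit = r_in + c.wall_thickness_mm  # sphere center on the outer wall
    for mk in spec.markers:
        ctr = _marker_center(spec, mk)
        d2 = (
            (x[None, None, :] - ctr[0]) ** 2
            + (y[None, :, None] - ctr[1]) ** 2
            + (z[:, None, None] - ctr[2]) ** 2
        )
        w = np.clip((mk.radius_mm - np.sqrt(d2)) / 0.5 + 0.5, 0.0, 1.0)
        field3d = field3d * (1.0 - w) + mk.marker_hu * w
    return field3d


def _marker_center(spec: PhantomSpec, mk: MarkerSpec) -> np.ndarray:
    c = spec.container
    orbit = c.inner_diameter_mm / 2.0 + c.wall_thickness_mm + mk.radius_mm
    t = np.deg2rad(mk.angle_deg)  # 0 deg = top (+y), 90 deg = +x
    return np.array([orbit * np.sin(t), orbit * np.cos(t), mk.z_mm])


def track_field(spec: PhantomSpec, lines: Sequence[Line3D]) -> np.ndarray:
    """Noiseless HU increment of the beam tracks along the given axes."""
    z, y, x = _grids(spec)
    X = x[None, None, :]
    Y = y[None, :, None]
    Z = z[:, None, None]
    r_in = spec.container.inner_diameter_mm / 2.0
    gel = (X**2 + Y**2) < r_in**2

    out = np.zeros(spec.shape)
    for beam, line in zip(spec.beams, lines):
        n_hat, l_hat = collimator_frame(line.direction, beam.collimator_deg)
        rx, ry, rz = X - line.point[0], Y - line.point[1], Z - line.point[2]
        s_n = rx * n_hat[0] + ry * n_hat[1] + rz * n_hat[2]
        s_l = rx * l_hat[0] + ry * l_hat[1] + rz * l_hat[2]
        dose = spec.gy_per_kmu * beam.mu / 1000.0
        amp = dose_to_hu(dose, spec.dose_model)
        prof = (
            amp
            * _erf_box(s_n, beam.gap_mm / 2.0, spec.penumbra_sigma_mm)
            * _erf_box(s_l, beam.field_length_mm / 2.0, spec.penumbra_sigma_mm)
        )
        out += np.where(gel, prof, 0.0)
    return out


def _scattered_lines(spec: PhantomSpec, rng: np.random.Generator) -> list[Line3D]:
    target = np.asarray(spec.target_point, float)
    lines = []
    for beam in spec.beams:
        d = beam_direction(beam.gantry_deg, beam.couch_deg)
        point = target.copy()
        if spec.beam_scatter_mm > 0:
            n_hat, l_hat = collimator_frame(d, 0.0)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            rho = rng.uniform(0.0, spec.beam_scatter_mm)
            point = target + rho * (np.cos(phi) * n_hat + np.sin(phi) * l_hat)
        lines.append(Line3D(point=point, direction=d))
    return lines


def simulate_phantom(
    spec: PhantomSpec,
) -> tuple[SeriesSet, SeriesSet, GroundTruth]:
    """Simulate background and irradiated series plus the ground truth.

    Each requested series is the shared noiseless field plus an
    independent draw of white Gaussian HU noise; the irradiated field
    adds the beam-track increments to the background field, so the
    noiseless difference of the two is exactly the track field.  The
    whole simulation is a pure function of the spec (seeded).
    """
    z, y, x = _grids(spec)
    tgt = np.asarray(spec.target_point, float)
    if not (
        x[0] <= tgt[0] <= x[-1] and y[0] <= tgt[1] <= y[-1] and z[0] <= tgt[2] <= z[-1]
    ):
        raise GeometryError(f"target point {tgt} lies outside the simulated volume")

    rng = np.random.default_rng(spec.seed)
    lines = _scattered_lines(spec, rng)

    bg = background_field(spec)
    irr = bg + track_field(spec, lines)

    def make_series(base: np.ndarray, n: int, label: str) -> SeriesSet:
        vols = []
        for _ in range(n):
            noise = (
                rng.normal(0.0, spec.noise_std_hu, size=base.shape)
                if spec.noise_std_hu > 0
                else 0.0
            )
            vols.append(spec.geometry_volume(base + noise))
        return SeriesSet(volumes=vols, label=label, mode_tag=spec.mode_tag)

    background = make_series(bg, spec.n_background_series, "background")
    irradiated = make_series(irr, spec.n_irradiated_series, "irradiated")

    marker_centers = [_marker_center(spec, mk) for mk in spec.markers]
    by_angle = {mk.angle_deg % 360.0: _marker_center(spec, mk) for mk in spec.markers}
    if {0.0, 90.0, 270.0} <= set(by_angle):
        reference = fiducial_reference_point(
            by_angle[0.0], by_angle[90.0], by_angle[270.0]
        )
    else:
        reference = tgt
    truth = GroundTruth(
        true_lines=lines,
        true_isocenter=tgt,
        marker_centers=marker_centers,
        reference_point=np.asarray(reference, float),
    )
    return background, irradiated, truth
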