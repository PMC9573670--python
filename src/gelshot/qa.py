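"""VOI statistics, image-uniformity arithmetic, profiles, scan scheduling.

The uniformity metric follows the installation-product-acceptance (IPA)
convention used with the Catphan uniformity module: the mean HU of four
peripheral cylindrical VOIs (left, top, right, bottom) minus the central
VOI mean, each compared against a +/-30 HU criterion, plus the mean of
the four differences per series and its mean across series.  Report
display rounds to 2 decimals, half away from zero.

The scan scheduler encodes the thermally-imposed acquisition rules:
a TrueBeam tolerates up to five consecutive scans with no gap, while a
Halcyon overheats its X-ray tube after two consecutive scans and needs a
cool-down gap before each further scan — 5 min in the Pelvis modes and
~6 min in the Pelvis Large modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, UsageError
from .volume_io import CTVolume

__all__ = [
    "VOICylinder",
    "UniformityRow",
    "UniformityReport",
    "ScanSchedule",
    "round_half_away",
    "voi_stats",
    "uniformity_ipa",
    "extract_profile",
    "schedule_scans",
    "UNIFORMITY_CRITERION_HU",
    "UNIFORMITY_POSITIONS",
]

UNIFORMITY_CRITERION_HU = 30.0
UNIFORMITY_POSITIONS = ("center", "left", "top", "right", "bottom")
_PERIPHERALS = ("left", "top", "right", "bottom")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed reports)."""
    scale = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale)


# ---------------------------------------------------------------------------
# VOI statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VOICylinder:
    """Cylindrical volume of interest (axis defaults to the volume z axis)."""

    center: tuple[float, float, float]
    diameter_mm: float
    length_mm: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise UsageError("diameter and length must be > 0")
        n = float(np.linalg.norm(self.axis))
        if n == 0:
            raise UsageError("axis must be non-zero")
        object.__setattr__(self, "axis", tuple(float(a) / n for a in self.axis))


def voi_stats(volume: CTVolume, voi: VOICylinder) -> tuple[float, float, int]:
    """(mean HU, sample Std HU, voxel count) over voxel centers in the VOI.

    The VOI must lie entirely inside the volume (checked on its bounding
    box); an empty VOI is a geometry error.
    """
    ctr = np.asarray(voi.center, float)
    ax = np.asarray(voi.axis, float)
    r = voi.diameter_mm / 2.0
    h = voi.length_mm / 2.0

    # bounding half-extent per axis of a capped cylinder
    half = np.abs(ax) * h + r * np.sqrt(np.maximum(1.0 - ax**2, 0.0))
    z_axis, y_axis, x_axis = volume.axis_coords()
    lo = np.array([x_axis[0], y_axis[0], z_axis[0]])
    hi = np.array([x_axis[-1], y_axis[-1], z_axis[-1]])
    if np.any(ctr - half < lo - 1e-9) or np.any(ctr + half > hi + 1e-9):
        raise GeometryError("VOI extends outside the volume")

    xx = x_axis[None, None, :] - ctr[0]
    yy = y_axis[None, :, None] - ctr[1]
    zz = z_axis[:, None, None] - ctr[2]
    along = xx * ax[0] + yy * ax[1] + zz * ax[2]
    r2 = xx**2 + yy**2 + zz**2 - along**2
    mask = (np.abs(along) <= h) & (r2 <= r**2)
    n = int(mask.sum())
    if n == 0:
        raise GeometryError("VOI contains no voxel centers")
    vals = volume.voxels[mask]
    std = float(vals.std(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), std, n


# ---------------------------------------------------------------------------
# IPA uniformity
# ---------------------------------------------------------------------------

@dataclass
class UniformityRow:
    """One series: five positional means, four diffs, their mean, verdicts."""

    means: dict[str, float]
    diffs: dict[str, float]
    mean_of_four: float
    verdicts: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.verdicts.values())


@dataclass
class UniformityReport:
    """Per-series uniformity rows plus the across-series mean and verdict."""

    rows: list[UniformityRow]
    series_mean: float
    criterion_hu: float = UNIFORMITY_CRITERION_HU

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_dict(self) -> dict:
        return {
            "criterion_hu": self.criterion_hu,
            "series_mean": self.series_mean,
            "passed": self.passed,
            "rows": [
                {
                    "means": r.means,
                    "diffs": r.diffs,
                    "mean_of_four": r.mean_of_four,
                    "verdicts": r.verdicts,
                }
                for r in self.rows
            ],
        }

    def to_frame(self):
        """Tabular layout mirroring the printed uniformity reports (2 dp)."""
        import pandas as pd

        rows = []
        for i, r in enumerate(self.rows, 1):
            rec = {"series": f"s_{i}"}
            rec.update(
                {p: round_half_away(r.means[p]) for p in UNIFORMITY_POSITIONS}
            )
            rec.update(
                {f"d_{p}": round_half_away(r.diffs[p]) for p in _PERIPHERALS}
            )
            rec["mean4"] = round_half_away(r.mean_of_four)
            rec["passed"] = r.passed
            rows.append(rec)
        frame = pd.DataFrame(rows)
        frame["series_mean"] = [round_half_away(self.series_mean)] + [None] * (
            len(rows) - 1
        )
        return frame


def uniformity_ipa(
    series_means: Sequence[Mapping[str, float]],
    criterion_hu: float = UNIFORMITY_CRITERION_HU,
) -> UniformityReport:
    """IPA uniformity from five positional VOI means per series.

    ``diff[p] = mean[p] - mean[center]`` for each peripheral position,
    ``mean_of_four`` averages the four diffs per series, and
    ``series_mean`` averages ``mean_of_four`` across the given series.
    A diff passes iff ``|diff| <= criterion_hu``.
    """
    if not series_means:
        raise UsageError("at least one series of means is required")
    rows = []
    for means in series_means:
        missing = [p for p in UNIFORMITY_POSITIONS if p not in means]
        if missing:
            raise UsageError(f"missing positional means: {missing}")
        m = {p: float(means[p]) for p in UNIFORMITY_POSITIONS}
        diffs = {p: m[p] - m["center"] for p in _PERIPHERALS}
        rows.append(
            UniformityRow(
                means=m,
                diffs=diffs,
                mean_of_four=float(np.mean([diffs[p] for p in _PERIPHERALS])),
                verdicts={p: abs(diffs[p]) <= criterion_hu for p in _PERIPHERALS},
            )
        )
    return UniformityReport(
        rows=rows,
        series_mean=float(np.mean([r.mean_of_four for r in rows])),
        criterion_hu=criterion_hu,
    )


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def extract_profile(
    volume: CTVolume,
    p0,
    p1,
    step_mm: float = 0.5,
    smooth: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear profile between two mm points.

    Returns ``(distance_mm, hu)`` sampled every ``step_mm`` including
    both endpoints; ``smooth`` applies a 1D mean filter of that odd
    kernel size.  Endpoints must be inside the volume.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if step_mm <= 0:
        raise UsageError("step_mm must be > 0")
    ni, nj, nk = volume.shape
    for p in (p0, p1):
        ijk = volume.mm_to_index(p)
        if np.any(ijk < -1e-9) or np.any(ijk > np.array([ni, nj, nk]) - 1 + 1e-9):
            raise GeometryError(f"profile endpoint {p} outside the volume")
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.floor(length / step_mm + 1e-9)) + 1, 2)
    t = np.linspace(0.0, length, n)
    pts = p0 + (p1 - p0) * (t / length if length > 0 else 0.0)[:, None]
    ijk = volume.mm_to_index(pts)
    vals = ndimage.map_coordinates(
        volume.voxels, ijk.T, order=1, mode="nearest"
    )
    if smooth is not None:
        if smooth < 1 or smooth % 2 == 0:
            raise UsageError("smooth kernel must be odd and >= 1")
        vals = ndimage.uniform_filter1d(vals, size=smooth, mode="reflect")
    return t, vals


# ---------------------------------------------------------------------------
# Scan scheduling
# ---------------------------------------------------------------------------

@dataclass
class ScanSchedule:
    """Inter-scan gaps (minutes) for a consecutive acquisition plan."""

    accelerator: str
    mode: str
    n_scans: int
    gaps_min: list[float]
    warning: str | None = None


def schedule_scans(accelerator: str, mode: str, n_scans: int) -> ScanSchedule:
    """Gap plan for ``n_scans`` consecutive scans.

    TrueBeam: no gaps needed for up to five scans.  Halcyon: only the
    first two scans may run back to back; every further scan needs a
    tube cool-down of 5 min (Pelvis modes) or 6 min (Pelvis Large
    modes).  More than five scans is outside the validated range and
    gets a warning.
    """
    if n_scans < 1:
        raise UsageError("n_scans must be >= 1")
    if accelerator not in ("TrueBeam", "Halcyon"):
        raise UsageError(f"unknown accelerator {accelerator!r}")
    if accelerator == "TrueBeam":
        gaps = [0.0] * (n_scans - 1)
    else:
        cool = 6.0 if "Pelvis Large" in mode else 5.0
        gaps = [0.0] * min(n_scans - 1, 1) + [cool] * max(n_scans - 2, 0)
    warning = (
        f"{n_scans} scans exceeds the validated range of 5 consecutive scans"
        if n_scans > 5
        else None
    )
    return ScanSchedule(
        accelerator=accelerator,
        mode=mode,
        n_scans=n_scans,
        gaps_min=gaps,
        warning=warning,
    )
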