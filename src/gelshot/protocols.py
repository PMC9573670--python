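"""Reference QA protocols as ready-made phantom specs and trial runners.

The reference star-shot protocol is the optimized gel-dosimeter
procedure: four coplanar slit beams (gantry 0/90/150/240 degrees, 2 mm
MLC gap, 10,000 MU each) through a 90 mm gel container, scanned three
times before and three times after irradiation at the lowest-noise
acquisition (iterative-reconstruction Pelvis preset), then mean-of-three
averaging, background subtraction, no filtering, and the star-shot fit
against the fiducial-derived reference point.

:func:`star_shot_trial` runs the whole chain in memory for one seed and
reports the recovered radius and the error against the simulation
ground truth — the package's primary self-validation, since real scans
of a given machine cannot ship with the code.
"""

from __future__ import annotations

import numpy as np

from .geometry import detect_beams_2d, detect_markers, fit_isocenter_2d
from .phantom import (
    BeamSpec,
    NOISE_PRESETS,
    PhantomSpec,
    simulate_phantom,
)
from .preprocess import average_series, subtract_background

__all__ = ["reference_star_phantom", "star_shot_trial"]

STAR_GANTRY_ANGLES = (0.0, 90.0, 150.0, 240.0)


def reference_star_phantom(
    seed: int,
    noise_std_hu: float | None = None,
    beam_scatter_mm: float = 0.0,
) -> PhantomSpec:
    """Phantom spec of the reference four-beam star-shot session."""
    if noise_std_hu is None:
        noise_std_hu = NOISE_PRESETS[("TrueBeam", "iCBCT", "Pelvis")]
    return PhantomSpec(
        beams=[BeamSpec(g, gap_mm=2.0, mu=10000.0) for g in STAR_GANTRY_ANGLES],
        noise_std_hu=noise_std_hu,
        beam_scatter_mm=beam_scatter_mm,
        n_background_series=3,
        n_irradiated_series=3,
        shape=(32, 112, 112),
        spacing=(2.0, 1.0, 1.0),
        seed=seed,
    )


def star_shot_trial(
    seed: int,
    noise_std_hu: float | None = None,
    beam_scatter_mm: float = 0.0,
    averaging: int = 3,
    slab_slices: int = 5,
) -> dict:
    """One full simulate -> preprocess -> detect -> fit star-shot run.

    Returns the fitted radius, the distance of the fitted center from
    the true isocenter, and the offset against the fiducial reference.
    """
    spec = reference_star_phantom(seed, noise_std_hu, beam_scatter_mm)
    bg, irr, truth = simulate_phantom(spec)
    bg_mean = average_series(bg, range(averaging))
    irr_mean = average_series(irr, range(averaging))
    sub = subtract_background(irr_mean, bg_mean)

    fids = detect_markers(irr_mean, (0.0, 90.0, 270.0), search_z=-1.0)
    z_axis, y_axis, x_axis = sub.axis_coords()
    i0 = int(np.argmin(np.abs(z_axis - fids.plane_z)))
    half = slab_slices // 2
    slab = sub.voxels[max(i0 - half, 0) : i0 + half + 1].mean(axis=0)

    lines = detect_beams_2d(
        slab, x_axis, y_axis, n_expected=len(spec.beams), gap_mm=2.0,
        plane_z=fids.plane_z,
    )
    result = fit_isocenter_2d(lines, reference=fids.reference_point[:2])
    center_error = float(
        np.linalg.norm(result.center - truth.true_isocenter[:2])
    )
    return {
        "radius_mm": float(result.radius_mm),
        "center_error_mm": center_error,
        "offset_mm": float(result.offset_mm),
        "tg142_pass": result.verdicts["tg142"],
        "result": result,
        "truth": truth,
    }
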