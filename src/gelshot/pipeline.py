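"""Configuration-driven end-to-end QA runs.

A :class:`PipelineConfig` names the input (either two DICOM series
directory sets of the same container — background and irradiated — or a
synthetic phantom spec), the processing protocol (how many series to
average, which filters, whether the background is filtered too), the
beam set, the fiducial/reference handling and the tolerances.  The run
functions execute

    average -> subtract background -> [filters] -> detect -> fit -> report

and write a machine-readable JSON report (embedding the resolved
configuration and software version), a per-beam CSV table and a log.
Exit status: 0 = within tolerance, 1 = tolerance exceeded, 2 = a stage
failed.

The default protocol reflects the optimized QA procedure: averaging
over up to three series, background subtraction on, no filtering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from .errors import GelshotError, UsageError
from .geometry import (
    MPC_OFFSET_TOLERANCE_MM,
    TG142_RADIUS_TOLERANCE_MM,
    IsocenterResult,
    detect_beams_2d,
    detect_beams_3d,
    detect_markers,
    fit_isocenter_2d,
    fit_isocenter_3d,
)
from .phantom import BeamSpec, PhantomSpec, beam_direction, simulate_phantom
from .preprocess import FilterSpec, apply_filter, average_series, subtract_background
from .qa import (
    UNIFORMITY_CRITERION_HU,
    VOICylinder,
    uniformity_ipa,
    voi_stats,
)
from .volume_io import CTVolume, SeriesSet, read_dicom_series_set

__all__ = [
    "PipelineConfig",
    "run_isocenter_2d",
    "run_isocenter_3d",
    "run_uniformity",
    "EXIT_PASS",
    "EXIT_TOLERANCE",
    "EXIT_STAGE_ERROR",
]

EXIT_PASS = 0
EXIT_TOLERANCE = 1
EXIT_STAGE_ERROR = 2

log = logging.getLogger("gelshot.pipeline")


@dataclass
class PipelineConfig:
    """Resolved run configuration (see module docstring)."""

    phantom: PhantomSpec | None = None
    background_dirs: list[str] = field(default_factory=list)
    irradiated_dirs: list[str] = field(default_factory=list)
    mode_tag: str = "TrueBeam/iCBCT/Pelvis"
    averaging: int = 3
    filters: list[FilterSpec] = field(default_factory=list)
    filter_background: bool = True
    beams: list[BeamSpec] = field(default_factory=list)
    marker_angles: tuple[float, float, float] = (0.0, 90.0, 270.0)
    marker_search_z: float = -1.0
    use_markers: bool = True
    reference_point: tuple[float, float, float] | None = None
    star_slab_slices: int = 5
    tg142_mm: float = TG142_RADIUS_TOLERANCE_MM
    mpc_mm: float = MPC_OFFSET_TOLERANCE_MM
    uniformity_voi_diameter_mm: float = 20.0
    uniformity_voi_length_mm: float = 5.0
    uniformity_radial_fraction: float = 0.8
    precomputed_uniformity_means: list[dict] = field(default_factory=list)
    output_dir: str = "gelshot_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tg142_mm <= 0 or self.mpc_mm <= 0:
            raise UsageError("tolerances must be > 0")
        has_dicom = bool(self.background_dirs or self.irradiated_dirs)
        if self.phantom is not None and has_dicom:
            raise UsageError("give either DICOM directories or a phantom spec, not both")
        if self.averaging < 1:
            raise UsageError("averaging must be >= 1")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("phantom") is not None:
            d["phantom"] = _phantom_from_dict(d["phantom"])
        if d.get("filters"):
            d["filters"] = [FilterSpec(**f) for f in d["filters"]]
        if d.get("beams"):
            d["beams"] = [BeamSpec(**b) for b in d["beams"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise UsageError(f"config {path} must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise UsageError(f"invalid config: {exc}") from exc

    def resolved(self) -> dict:
        """JSON-serializable copy of the full configuration."""
        d = asdict(self)
        return json.loads(json.dumps(d, default=_jsonable, sort_keys=True))


def _phantom_from_dict(d: dict) -> PhantomSpec:
    from .phantom import ContainerSpec, DoseModel, MarkerSpec

    d = dict(d)
    if "container" in d and isinstance(d["container"], dict):
        d["container"] = ContainerSpec(**d["container"])
    if "dose_model" in d and isinstance(d["dose_model"], dict):
        d["dose_model"] = DoseModel(**d["dose_model"])
    if "beams" in d:
        d["beams"] = [
            b if isinstance(b, BeamSpec) else BeamSpec(**b) for b in d["beams"]
        ]
    if "markers" in d:
        d["markers"] = tuple(
            m if isinstance(m, MarkerSpec) else MarkerSpec(**m) for m in d["markers"]
        )
    for key in ("target_point", "shape", "spacing"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)


# ---------------------------------------------------------------------------
# Input loading and shared stages
# ---------------------------------------------------------------------------

def _load_inputs(config: PipelineConfig):
    """(background SeriesSet, irradiated SeriesSet, GroundTruth | None)."""
    if config.phantom is not None:
        spec = config.phantom
        bg, irr, truth = simulate_phantom(spec)
        if not config.beams:
            config.beams = list(spec.beams)
        return bg, irr, truth
    if not (config.background_dirs and config.irradiated_dirs):
        raise UsageError("need both background and irradiated DICOM directories")
    bg = read_dicom_series_set(config.background_dirs, "background", config.mode_tag)
    irr = read_dicom_series_set(config.irradiated_dirs, "irradiated", config.mode_tag)
    # the protocol scans the same container in place: adopt the background
    # frame token once the grids agree geometrically (no registration is done)
    from dataclasses import replace

    a, b = bg.volumes[0], irr.volumes[0]
    if a.shape == b.shape and np.allclose(a.spacing, b.spacing) and np.allclose(
        a.origin, b.origin
    ):
        irr = SeriesSet(
            volumes=[replace(v, frame_id=a.frame_id) for v in irr.volumes],
            label="irradiated",
            mode_tag=irr.mode_tag,
        )
    return bg, irr, None


def _preprocess(config: PipelineConfig, bg: SeriesSet, irr: SeriesSet):
    """Average, optionally filter (symmetric by default), subtract."""
    n = min(config.averaging, len(bg), len(irr))
    bg_mean = average_series(bg, range(min(config.averaging, len(bg))))
    irr_mean = average_series(irr, range(min(config.averaging, len(irr))))
    log.info("averaged %d background and irradiated series", n)
    for spec in config.filters:
        irr_mean = apply_filter(irr_mean, spec)
        if config.filter_background:
            bg_mean = apply_filter(bg_mean, spec)
        else:
            log.warning(
                "filter %r applied to the irradiated image only: subtracting an "
                "unfiltered background can leave ring artifacts on the result",
                spec.name,
            )
    return bg_mean, irr_mean, subtract_background(irr_mean, bg_mean)


def _reference(config: PipelineConfig, raw_volume: CTVolume):
    """Reference point: explicit override, else fiducial construction."""
    if config.reference_point is not None:
        return np.asarray(config.reference_point, float), None
    if not config.use_markers:
        return None, None
    fids = detect_markers(
        raw_volume, config.marker_angles, search_z=config.marker_search_z
    )
    return fids.reference_point, fids


# ---------------------------------------------------------------------------
# Report plumbing
# ---------------------------------------------------------------------------

def _write_report(
    config: PipelineConfig, name: str, payload: dict, per_beam_rows: list[dict] | None
) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "tool": {"name": "gelshot", "version": __version__},
        "config": config.resolved(),
        **payload,
    }
    (outdir / f"{name}.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    if per_beam_rows:
        import pandas as pd

        pd.DataFrame(per_beam_rows).to_csv(outdir / f"{name}_beams.csv", index=False)
    return report


def _setup_log(config: PipelineConfig, name: str) -> logging.Handler:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / f"{name}.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("gelshot").addHandler(handler)
    logging.getLogger("gelshot").setLevel(logging.INFO)
    return handler


def _teardown_log(handler: logging.Handler) -> None:
    logging.getLogger("gelshot").removeHandler(handler)
    handler.close()


def _isocenter_payload(result: IsocenterResult, extra: dict) -> dict:
    payload = {"isocenter": result.to_dict(), **extra}
    return payload


def _exit_code(result: IsocenterResult) -> int:
    return EXIT_PASS if result.passed else EXIT_TOLERANCE


# ---------------------------------------------------------------------------
# Runs
# ---------------------------------------------------------------------------

def run_isocenter_2d(config: PipelineConfig) -> tuple[dict, int]:
    """Star-shot run: 2D line detection in a transversal slab and the
    smallest-touching-circle fit.  Requires >= 3 coplanar beams."""
    handler = _setup_log(config, "isocenter2d")
    try:
        bg, irr, truth = _load_inputs(config)
        if len(config.beams) < 3:
            raise UsageError("the star-shot run needs at least 3 beams")
        if any(abs(b.couch_deg) > 1e-9 for b in config.beams):
            raise UsageError("star-shot beams must be coplanar (couch at 0)")
        bg_mean, irr_mean, sub = _preprocess(config, bg, irr)
        reference, fids = _reference(config, irr_mean)

        plane_z = fids.plane_z if fids is not None else (
            float(reference[2]) if reference is not None and len(reference) > 2 else 0.0
        )
        z_axis, y_axis, x_axis = sub.axis_coords()
        i0 = int(np.argmin(np.abs(z_axis - plane_z)))
        half = config.star_slab_slices // 2
        sl = slice(max(i0 - half, 0), min(i0 + half + 1, sub.shape[0]))
        slab = sub.voxels[sl].mean(axis=0)
        log.info("star slab: slices %s around z=%.2f mm", sl, plane_z)

        gap = float(np.median([b.gap_mm for b in config.beams]))
        lines = detect_beams_2d(
            slab, x_axis, y_axis, n_expected=len(config.beams), gap_mm=gap,
            plane_z=plane_z,
        )
        ref2d = None if reference is None else np.asarray(reference, float)[:2]
        result = fit_isocenter_2d(
            lines, reference=ref2d,
            tg142_tolerance_mm=config.tg142_mm, mpc_tolerance_mm=config.mpc_mm,
        )
        rows = [
            {
                "beam": i,
                "angle_deg": ln.angle_deg,
                "offset_c_mm": ln.c,
                "distance_to_center_mm": float(d),
            }
            for i, (ln, d) in enumerate(zip(lines, result.per_beam_distance_mm))
        ]
        extra = {
            "mode": "star_shot_2d",
            "plane_z_mm": plane_z,
            "lines": [
                {"a": ln.a, "b": ln.b, "c": ln.c, "angle_deg": ln.angle_deg}
                for ln in lines
            ],
            "reference_point_mm": None if reference is None else list(map(float, reference)),
        }
        if truth is not None:
            extra["ground_truth_isocenter_mm"] = [float(v) for v in truth.true_isocenter]
        report = _write_report(config, "isocenter2d", _isocenter_payload(result, extra), rows)
        return report, _exit_code(result)
    except GelshotError as exc:
        log.error("stage failure: %s", exc)
        report = _write_report(
            config, "isocenter2d", {"mode": "star_shot_2d", "error": str(exc)}, None
        )
        return report, EXIT_STAGE_ERROR
    finally:
        _teardown_log(handler)


def run_isocenter_3d(config: PipelineConfig) -> tuple[dict, int]:
    """3D run: guided line detection per planned beam and the smallest
    sphere touching all axes; offset against the fiducial reference."""
    handler = _setup_log(config, "isocenter3d")
    try:
        bg, irr, truth = _load_inputs(config)
        if len(config.beams) < 2:
            raise UsageError("the 3D run needs at least 2 beams")
        bg_mean, irr_mean, sub = _preprocess(config, bg, irr)
        reference, fids = _reference(config, irr_mean)

        dirs = [beam_direction(b.gantry_deg, b.couch_deg) for b in config.beams]
        coplanar = bool(
            np.linalg.matrix_rank(np.stack(dirs), tol=1e-6) <= 2
        )
        if coplanar:
            log.warning("all planned beams are coplanar; a 3D fit is ill-conditioned "
                        "along the plane normal")
        gap = float(np.median([b.gap_mm for b in config.beams]))
        lines = detect_beams_3d(sub, dirs, gap_mm=gap)
        result = fit_isocenter_3d(
            lines, reference=reference,
            tg142_tolerance_mm=config.tg142_mm, mpc_tolerance_mm=config.mpc_mm,
        )
        rows = [
            {
                "beam": i,
                "gantry_deg": b.gantry_deg,
                "couch_deg": b.couch_deg,
                "distance_to_center_mm": float(d),
            }
            for i, (b, d) in enumerate(zip(config.beams, result.per_beam_distance_mm))
        ]
        extra = {
            "mode": "isocenter_3d",
            "coplanar_warning": coplanar,
            "lines": [
                {"point_mm": ln.point.tolist(), "direction": ln.direction.tolist()}
                for ln in lines
            ],
            "reference_point_mm": None if reference is None else list(map(float, reference)),
        }
        if truth is not None:
            extra["ground_truth_isocenter_mm"] = [float(v) for v in truth.true_isocenter]
        report = _write_report(config, "isocenter3d", _isocenter_payload(result, extra), rows)
        return report, _exit_code(result)
    except GelshotError as exc:
        log.error("stage failure: %s", exc)
        report = _write_report(
            config, "isocenter3d", {"mode": "isocenter_3d", "error": str(exc)}, None
        )
        return report, EXIT_STAGE_ERROR
    finally:
        _teardown_log(handler)


def run_uniformity(config: PipelineConfig) -> tuple[dict, int]:
    """Uniformity run: five cylindrical VOIs per series (center plus four
    peripherals at a fixed radial offset) fed into the IPA arithmetic.

    With ``precomputed_uniformity_means`` set, the positional means are
    taken as given (e.g. from a printed report) and only the derived
    arithmetic is computed.
    """
    handler = _setup_log(config, "uniformity")
    try:
        if config.precomputed_uniformity_means:
            report_obj = uniformity_ipa(config.precomputed_uniformity_means)
        else:
            series, _, _ = _load_inputs(config)
            if config.phantom is not None:
                radius = config.phantom.container.inner_diameter_mm / 2.0
                z0 = 0.0
            else:
                radius = 0.5 * config.uniformity_voi_diameter_mm / 0.8
                z0 = 0.0
            offset = config.uniformity_radial_fraction * radius - (
                config.uniformity_voi_diameter_mm / 2.0
            )
            offset = max(offset, config.uniformity_voi_diameter_mm / 2.0)
            pos = {
                "center": (0.0, 0.0, z0),
                "left": (-offset, 0.0, z0),
                "top": (0.0, offset, z0),
                "right": (offset, 0.0, z0),
                "bottom": (0.0, -offset, z0),
            }
            means = []
            for vol in series.volumes:
                row = {}
                for name, ctr in pos.items():
                    voi = VOICylinder(
                        center=ctr,
                        diameter_mm=config.uniformity_voi_diameter_mm,
                        length_mm=config.uniformity_voi_length_mm,
                    )
                    row[name], _, _ = voi_stats(vol, voi)
                means.append(row)
            report_obj = uniformity_ipa(means)
        payload = {"mode": "uniformity", "uniformity": report_obj.to_dict()}
        report = _write_report(config, "uniformity", payload, None)
        outdir = Path(config.output_dir)
        report_obj.to_frame().to_csv(outdir / "uniformity.csv", index=False)
        code = EXIT_PASS if report_obj.passed else EXIT_TOLERANCE
        return report, code
    except GelshotError as exc:
        log.error("stage failure: %s", exc)
        report = _write_report(
            config, "uniformity", {"mode": "uniformity", "error": str(exc)}, None
        )
        return report, EXIT_STAGE_ERROR
    finally:
        _teardown_log(handler)
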