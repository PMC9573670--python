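"""CT volume container and I/O.

A :class:`CTVolume` is a 3D grid of Hounsfield units together with the
affine map that places every voxel in a millimetre patient frame.  The
frame is right-handed and DICOM-like:

* ``z`` runs along the couch / scanner rotation axis (the slice axis),
* ``y`` is vertical (up),
* ``x`` is lateral.

Voxels are stored ``(slice, row, col)`` and voxel *centers* carry
positions: ``mm(i, j, k) = origin + (k*sx, j*sy, i*sz)`` in ``(x, y, z)``
order.  Two volumes are *co-registered* iff shape, spacing, origin and
``frame_id`` all agree; background subtraction and series averaging
require it and no image registration is ever attempted.

DICOM series are read with :mod:`pydicom` (single-frame CT, one series
per directory, axial identity orientation); the portable intermediate
format is NIfTI via :mod:`nibabel`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom

from .errors import FormatError, GeometryError, UsageError

__all__ = [
    "CTVolume",
    "SeriesSet",
    "read_dicom_series",
    "read_volume",
    "write_volume",
    "assert_coregistered",
]

_AXIAL_ORIENT = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


@dataclass
class CTVolume:
    """3D HU grid with spacing/origin defining a mm frame.

    Parameters
    ----------
    voxels : ndarray, shape (n_slice, n_row, n_col)
        Hounsfield units, finite.
    spacing : (sz, sy, sx)
        Voxel pitch in mm along slice/row/col, all > 0.
    origin : (x0, y0, z0)
        mm position of the center of voxel ``(0, 0, 0)``.
    frame_id : str
        Opaque geometry token; volumes from different scan sessions get
        different tokens and refuse voxelwise combination.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    frame_id: str = "default"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D array (slice, row, col)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("voxels contain non-finite values")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_mm(self, i, j, k) -> np.ndarray:
        """mm position (x, y, z) of voxel center (i=slice, j=row, k=col)."""
        sz, sy, sx = self.spacing
        x0, y0, z0 = self.origin
        return np.stack(
            [x0 + np.asarray(k) * sx, y0 + np.asarray(j) * sy, z0 + np.asarray(i) * sz],
            axis=-1,
        )

    def mm_to_index(self, xyz) -> np.ndarray:
        """Fractional (i, j, k) voxel index of mm point(s) (x, y, z)."""
        xyz = np.asarray(xyz, dtype=float)
        sz, sy, sx = self.spacing
        x0, y0, z0 = self.origin
        return np.stack(
            [(xyz[..., 2] - z0) / sz, (xyz[..., 1] - y0) / sy, (xyz[..., 0] - x0) / sx],
            axis=-1,
        )

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(z of slices, y of rows, x of cols) in mm."""
        sz, sy, sx = self.spacing
        x0, y0, z0 = self.origin
        ni, nj, nk = self.shape
        return (
            z0 + np.arange(ni) * sz,
            y0 + np.arange(nj) * sy,
            x0 + np.arange(nk) * sx,
        )

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """Same geometry, new voxel data."""
        if voxels.shape != self.voxels.shape:
            raise GeometryError("replacement voxels must keep the shape")
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))

    def is_coregistered(self, other: "CTVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and self.frame_id == other.frame_id
        )


@dataclass
class SeriesSet:
    """Ordered, co-registered scan series of one container.

    ``label`` distinguishes the non-irradiated background set from the
    irradiated set; ``mode_tag`` carries accelerator+mode provenance
    (e.g. ``"TrueBeam/iCBCT/Pelvis"``).
    """

    volumes: list[CTVolume]
    label: str = "background"
    mode_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.volumes) < 1:
            raise UsageError("a SeriesSet needs at least one volume")
        if self.label not in ("background", "irradiated"):
            raise UsageError(f"label must be background|irradiated, got {self.label!r}")
        for v in self.volumes[1:]:
            assert_coregistered(self.volumes[0], v)

    def __len__(self) -> int:
        return len(self.volumes)

    def __getitem__(self, i: int) -> CTVolume:
        return self.volumes[i]


def assert_coregistered(a: CTVolume, b: CTVolume, atol: float = 1e-6) -> None:
    """Raise :class:`GeometryError` naming the first mismatching field."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=atol):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, atol=atol):
        raise GeometryError(f"origin mismatch: {a.origin} vs {b.origin}")
    if a.frame_id != b.frame_id:
        raise GeometryError(f"frame_id mismatch: {a.frame_id!r} vs {b.frame_id!r}")


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _dicom_files(directory: str | Path) -> list[Path]:
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no files in {directory}")
    return files


def read_dicom_series(directory_path: str | Path) -> CTVolume:
    """Read one single-frame CT series from a directory into HU.

    Slices are sorted by position along the slice normal regardless of
    filename order; ``HU = stored * RescaleSlope + RescaleIntercept``.
    The origin is the ImagePositionPatient of the first (lowest) slice,
    i.e. the center of voxel (0, 0, 0).

    Raises
    ------
    FormatError
        Mixed SeriesInstanceUIDs, missing rescale tags, inconsistent
        rows/cols/pixel spacing or a non-axial orientation.
    GeometryError
        Inter-slice gaps deviating more than 1 % from uniform.
    """
    datasets = []
    for p in _dicom_files(directory_path):
        try:
            ds = pydicom.dcmread(p)
        except Exception as exc:  # unreadable file in the series directory
            raise FormatError(f"cannot read {p} as DICOM: {exc}") from exc
        datasets.append(ds)

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"mixed SeriesInstanceUIDs in directory: {sorted(uids)}")

    ref = datasets[0]
    for ds in datasets:
        if (ds.Rows, ds.Columns) != (ref.Rows, ref.Columns):
            raise FormatError("inconsistent Rows/Columns across slices")
        if not np.allclose([float(v) for v in ds.PixelSpacing],
                           [float(v) for v in ref.PixelSpacing]):
            raise FormatError("inconsistent PixelSpacing across slices")
        orient = np.array([float(v) for v in ds.ImageOrientationPatient])
        if not np.allclose(orient, _AXIAL_ORIENT, atol=1e-6):
            raise FormatError("only axial identity orientation is supported")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise FormatError("missing RescaleSlope/RescaleIntercept")

    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    order = np.argsort(zpos)
    datasets = [datasets[i] for i in order]
    zpos = zpos[order]

    if len(datasets) > 1:
        gaps = np.diff(zpos)
        if np.any(gaps <= 0):
            raise GeometryError("duplicate or coincident slice positions")
        mean_gap = float(gaps.mean())
        if np.any(np.abs(gaps - mean_gap) > 0.01 * mean_gap):
            raise GeometryError(
                f"non-uniform slice spacing: gaps {gaps.min():.4f}..{gaps.max():.4f} mm"
            )
        sz = mean_gap
    else:
        sz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    sy, sx = (float(v) for v in ref.PixelSpacing)  # row pitch, col pitch
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slices.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    voxels = np.stack(slices, axis=0)

    ipp = [float(v) for v in datasets[0].ImagePositionPatient]
    frame = getattr(ref, "FrameOfReferenceUID", None) or next(iter(uids))
    return CTVolume(
        voxels=voxels,
        spacing=(sz, sy, sx),
        origin=(ipp[0], ipp[1], ipp[2]),
        frame_id=str(frame),
    )


def read_dicom_series_set(
    directories: Sequence[str | Path], label: str, mode_tag: str = ""
) -> SeriesSet:
    """Read several series directories of the same container into a SeriesSet."""
    vols = [read_dicom_series(d) for d in directories]
    # one scan session: unify the frame token so co-registration can hold
    token = hashlib.sha1("|".join(v.frame_id for v in vols).encode()).hexdigest()[:12]
    vols = [replace(v, frame_id=token) for v in vols]
    return SeriesSet(volumes=vols, label=label, mode_tag=mode_tag)


# ---------------------------------------------------------------------------
# Portable volume format (NIfTI)
# ---------------------------------------------------------------------------

def write_volume(volume: CTVolume, path: str | Path, format: str = "nifti") -> Path:
    """Write a volume to the portable research format (NIfTI-1).

    The affine encodes spacing and origin; ``frame_id`` (up to 79 chars)
    rides in the descrip header field so round trips stay co-registered.
    """
    if format not in ("nifti", "nii"):
        raise UsageError(f"unsupported format: {format!r}")
    path = Path(path)
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0]).astype(float)
    affine[:3, 3] = volume.origin
    # NIfTI index order is (x, y, z); our voxels are (z, y, x)
    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0).astype(np.float32))
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = volume.frame_id.encode()[:79]
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI volume written by :func:`write_volume`."""
    img = nib.load(str(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise FormatError("only axis-aligned affines are supported")
    sx, sy, sz = (float(affine[i, i]) for i in range(3))
    if min(sx, sy, sz) <= 0:
        raise FormatError("affine must have positive diagonal scales")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    frame = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode() or "default"
    return CTVolume(
        voxels=data.transpose(2, 1, 0),
        spacing=(sz, sy, sx),
        origin=tuple(float(v) for v in affine[:3, 3]),
        frame_id=frame,
    )
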