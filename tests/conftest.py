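"""Shared fixtures: synthetic DICOM series writer and small phantom specs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from gelshot import BeamSpec, ContainerSpec, PhantomSpec


def write_dicom_series(
    directory: Path,
    voxels: np.ndarray,
    spacing=(2.0, 0.9, 0.9),
    origin=(-45.0, -45.0, -10.0),
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str | None = None,
    shuffle_names: bool = False,
    drop_slice: int | None = None,
    prefix: str = "",
) -> Path:
    """Write a (slice, row, col) array as a single-frame CT series.

    Stored values are chosen so that ``stored * slope + intercept``
    reproduces ``voxels`` exactly (``voxels`` must be representable).
    """
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    frame_uid = generate_uid()
    sz, sy, sx = spacing
    n = voxels.shape[0]
    name_order = np.arange(n)
    if shuffle_names:
        name_order = np.random.default_rng(0).permutation(n)
    for i in range(n):
        if drop_slice is not None and i == drop_slice:
            continue
        stored = np.round((voxels[i] - intercept) / slope).astype(np.int16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = stored.shape
        ds.PixelSpacing = [sy, sx]
        ds.SliceThickness = sz
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [origin[0], origin[1], origin[2] + i * sz]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = stored.tobytes()
        ds.save_as(
            directory / f"{prefix}slice_{name_order[i]:03d}.dcm",
            enforce_file_format=True,
        )
    return directory


@pytest.fixture
def dicom_writer():
    return write_dicom_series


@pytest.fixture
def hu_stack(seed: int = 0) -> np.ndarray:
    """Small integer-valued HU stack exactly representable via rescale."""
    rng = np.random.default_rng(11)
    return rng.integers(-1000, 1500, size=(10, 16, 16)).astype(float)


def small_star_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Compact four-beam star phantom (80 mm container) for fast tests."""
    kwargs = dict(
        container=ContainerSpec(inner_diameter_mm=80.0, length_mm=90.0),
        beams=[BeamSpec(g) for g in (0.0, 90.0, 150.0, 240.0)],
        shape=(16, 96, 96),
        spacing=(2.0, 1.0, 1.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture
def star_spec() -> PhantomSpec:
    return small_star_spec()


@pytest.fixture
def star_spec_factory():
    return small_star_spec
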