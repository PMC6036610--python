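"""Shared fixtures: small masks, random blobs, and a synthetic DICOM series."""

import os

import numpy as np
import pytest

from residualstl import BinaryMask, extract_surface


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return BinaryMask(data=np.asarray(data, bool), spacing=np.asarray(spacing, float),
                      origin=np.asarray(origin, float))


def solid_block(shape, spacing=(1.0, 1.0, 1.0)):
    return make_mask(np.ones(shape, bool), spacing)


def random_blob(rng, shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0), min_voxels=500):
    """A connected random blob: a thresholded smoothed noise field, largest
    component kept, regrown until it has at least ``min_voxels`` voxels."""
    from scipy import ndimage

    for _ in range(50):
        field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
        mask = field > np.quantile(field, 0.75)
        labels, n = ndimage.label(mask)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        blob = labels == counts.argmax()
        if blob.sum() >= min_voxels:
            return make_mask(blob, spacing)
    raise RuntimeError("could not grow a blob of the requested size")


def sphere_mask(radius_mm, spacing_mm, margin=2):
    n = int(2 * (radius_mm / spacing_mm + margin)) + 1
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2.0
    r2 = ((idx - c) ** 2).sum(axis=0) * spacing_mm ** 2
    return make_mask(r2 <= radius_mm ** 2, (spacing_mm,) * 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_cube_mesh():
    """A 1 mm cube as a 12-face mesh from a single voxel."""
    return extract_surface(solid_block((1, 1, 1)))


def write_dicom_series(dirpath, n_slices=4, shape=(8, 8), series_uid=None,
                       z_positions=None, slope=1.0, intercept=-1024.0, value=1024,
                       pixel_spacing=(0.5, 0.5)):
    """Write a minimal synthetic CT DICOM series for I/O tests."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    if z_positions is None:
        z_positions = [i * 0.5 for i in range(n_slices)]
    existing = len([f for f in os.listdir(dirpath) if f.endswith(".dcm")])
    for i, z in enumerate(z_positions):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "synthetic"
        ds.Rows, ds.Columns = shape
        ds.PixelSpacing = list(pixel_spacing)
        ds.SliceThickness = 0.5
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = i + 1
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        arr = np.full(shape, value, dtype=np.uint16)
        ds.PixelData = arr.tobytes()
        ds.save_as(os.path.join(dirpath, f"slice{existing + i:03d}.dcm"),
                   enforce_file_format=True)
    return series_uid
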