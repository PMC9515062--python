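"""Shared fixtures: default geometries and small rendered scenes."""

import numpy as np
import pytest

from fidloc import (
    RigidTransform,
    ct_profile,
    default_geometry,
    render_marker_volume,
)


@pytest.fixture(scope="session")
def geo315():
    return default_geometry("3_15")


@pytest.fixture(scope="session")
def geo620():
    return default_geometry("6_20")


@pytest.fixture(scope="session")
def scene_pose():
    return RigidTransform.from_euler_degrees((25.0, 10.0, -15.0), (12.0, -7.0, 30.0))


@pytest.fixture(scope="session")
def clean_scene(geo315, scene_pose):
    """Noiseless CT render of the 3_15 marker at 1 mm slices."""
    volume, truth = render_marker_volume(
        geo315, scene_pose, ct_profile(noise_sd=0.0, seed=1),
        spacing=(0.98, 0.98, 1.0),
    )
    return volume, truth


@pytest.fixture(scope="session")
def thick_scene(geo315, scene_pose):
    """Same scene reconstructed at 5 mm slice thickness/spacing."""
    volume, truth = render_marker_volume(
        geo315, scene_pose, ct_profile(noise_sd=0.0, seed=1),
        spacing=(0.98, 0.98, 5.0),
    )
    return volume, truth


def write_dicom_series(
    dirpath,
    voxels_zyx: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    orientation=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0),
    skip_slice: int | None = None,
    declared_gap: float | None = None,
):
    """Write a synthetic CT DICOM series for reader tests."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ct_storage = "1.2.840.10008.5.1.4.1.1.2"
    study, series, frame = generate_uid(), generate_uid(), generate_uid()
    row = np.asarray(orientation[:3], float)
    col = np.asarray(orientation[3:], float)
    normal = np.cross(row, col)
    nz, ny, nx = voxels_zyx.shape
    for k in range(nz):
        if skip_slice is not None and k == skip_slice:
            continue
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ct_storage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = ct_storage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "00"
        ds.Modality = "CT"
        ds.StudyInstanceUID = study
        ds.SeriesInstanceUID = series
        ds.FrameOfReferenceUID = frame
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [float(v) for v in orientation]
        pos = np.asarray(origin, float) + k * spacing[2] * normal
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.PixelSpacing = [float(spacing[1]), float(spacing[0])]
        ds.SliceThickness = float(spacing[2])
        if declared_gap is not None:
            ds.SpacingBetweenSlices = float(declared_gap)
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(voxels_zyx[k], dtype=np.uint16).tobytes()
        ds.save_as(dirpath / f"slice_{k:03d}.dcm", enforce_file_format=True)
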