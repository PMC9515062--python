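"""Reading, writing and geometry of 3D medical volumes.

The world frame is LPS (the DICOM patient convention), millimetres.
SimpleITK is used for all formats — MetaImage (.mha/.mhd), NIfTI
(.nii/.nii.gz, converted from its native RAS into LPS by the reader) and
DICOM series directories — so every reader maps into the same convention.

Voxel indices are 0-based and ordered (i, j, k) = (x, y, z); the world
position of index (0, 0, 0) is the *center* of the first voxel.  The voxel
array itself is stored in numpy (z, y, x) order, matching
``SimpleITK.GetArrayFromImage``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import VolumeIOError

_DIRECTION_TOL = 1e-6


@dataclass
class Volume:
    """A 3D scalar grid with world geometry.

    ``voxels`` is indexed ``[z, y, x]``; ``spacing``, ``origin`` are
    (x, y, z)-ordered mm vectors; ``direction`` is the 3x3 orthonormal
    matrix whose columns are the world directions of the x, y, z index
    axes.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality_hint: str = "unknown"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if np.abs(self.direction.T @ self.direction - np.eye(3)).max() > _DIRECTION_TOL:
            raise ValueError("direction matrix is not orthonormal")

    # -- derived geometry --------------------------------------------------
    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.voxels.shape
        return nx, ny, nz

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def voxel_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of a continuous (x, y, z) voxel index."""
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_voxel(self, point) -> np.ndarray:
        """Continuous (x, y, z) voxel index of a world point (mm)."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.direction) / self.spacing

    # -- SimpleITK bridge --------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.voxels)
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality_hint: str = "unknown") -> "Volume":
        return cls(
            voxels=sitk.GetArrayFromImage(img),
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
            modality_hint=modality_hint,
        )


def _validate_dicom_series(files: list[str]) -> None:
    """Check orientation consistency and uniform slice spacing with pydicom.

    Slice spacing is taken from inter-slice positions; a warning is issued
    when DICOM tag (0018,0088) SpacingBetweenSlices disagrees with the
    measured value.
    """
    import pydicom

    headers = [pydicom.dcmread(f, stop_before_pixels=True) for f in files]
    orientations = np.array(
        [np.asarray(h.ImageOrientationPatient, dtype=float) for h in headers]
    )
    if np.ptp(orientations, axis=0).max() > 1e-4:
        raise VolumeIOError("DICOM series has inconsistent slice orientations")
    row, col = orientations[0][:3], orientations[0][3:]
    normal = np.cross(row, col)
    pos = np.array(
        [np.asarray(h.ImagePositionPatient, dtype=float) @ normal for h in headers]
    )
    pos = np.sort(pos)
    if len(pos) >= 2:
        gaps = np.diff(pos)
        spacing = np.median(gaps)
        if spacing <= 0:
            raise VolumeIOError("DICOM series has duplicate slice positions")
        if np.abs(gaps - spacing).max() > 0.05 * spacing:
            raise VolumeIOError(
                "non-uniform slice spacing in DICOM series "
                f"(gaps {gaps.min():.3f}..{gaps.max():.3f} mm)"
            )
        declared = getattr(headers[0], "SpacingBetweenSlices", None)
        if declared is not None and abs(float(declared) - spacing) > 0.05 * spacing:
            warnings.warn(
                f"DICOM tag (0018,0088) declares {float(declared):.3f} mm but "
                f"inter-slice positions measure {spacing:.3f} mm; "
                "using the measured value",
                stacklevel=3,
            )
        thickness = getattr(headers[0], "SliceThickness", None)
        if thickness is not None and abs(float(thickness) - spacing) > 0.05 * spacing:
            warnings.warn(
                "slice thickness differs from slice spacing; features may "
                "not be completely captured",
                stacklevel=3,
            )


def _read_dicom_series(path: Path) -> Volume:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise VolumeIOError(f"no DICOM series found in {path}")
    _validate_dicom_series(list(files))
    reader.SetFileNames(files)
    reader.MetaDataDictionaryArrayUpdateOn()
    img = reader.Execute()
    modality = "unknown"
    try:
        modality = reader.GetMetaData(0, "0008|0060").strip() or "unknown"
    except Exception:
        pass
    if modality == "MR":
        modality = "MRI"
    return Volume.from_sitk(img, modality_hint=modality)


def read_volume(path: str | Path) -> Volume:
    """Read a MetaImage/NIfTI file or a DICOM series directory.

    World geometry (spacing, origin, direction) is preserved; a missing or
    invalid geometry raises :class:`VolumeIOError` rather than being
    silently defaulted.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise VolumeIOError(f"volume not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeIOError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeIOError(f"{path} is not a 3D volume")
    return Volume.from_sitk(img)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume (format chosen by extension; MetaImage recommended)."""
    try:
        sitk.WriteImage(volume.to_sitk(), str(path), useCompression=False)
    except RuntimeError as exc:
        raise VolumeIOError(f"could not write {path}: {exc}") from exc
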