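"""Marker configurations and their pairwise-distance structure.

A fiducial marker carries eight spherical features distributed over two
parallel planes, four per plane.  The feature centroids form a distance
configuration in which every one of the 28 pairwise distances — and hence
every per-feature distance signature — is unique at a stated tolerance.
That uniqueness is what lets the localization algorithm establish
candidate-to-feature correspondence from distances alone, without any
initialization.

Configurations are named ``<diameter>_<min distance>``: ``3_15`` has 3 mm
features with a minimal centroid spacing of 15 mm.  The shipped default
coordinate sets satisfy all invariants by construction and are validated,
not assumed, on load.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.spatial.distance import pdist

from .errors import GeometryError

#: Default tolerance (mm) at which pairwise distances / signatures must be
#: unique.  Roughly one in-plane CT voxel; the matcher's distance tolerance
#: must stay above the centroid estimation error, so ambiguity below this
#: scale would break correspondence finding.
DEFAULT_TAU = 1.0

#: Tolerance (mm) for the two-parallel-planes invariant.
PLANARITY_TOL = 0.5

# Shipped default feature centroids (mm, marker coordinate system).  Two
# parallel planes 10 mm apart, four features per plane, centred on the
# centroid.  Found by numerical search so that the minimum pairwise
# distance is exactly 15 / 20 mm and all 28 pairwise distances are
# mutually separated by > 1.5 mm (unique at tau = 1.0 mm with margin).
_POINTS_MIN15 = np.array([
    [32.8623, 20.4440, -5.0],
    [-32.6023, -53.8582, -5.0],
    [-15.7539, 7.6594, -5.0],
    [18.3030, 8.7070, -5.0],
    [-13.7355, -3.3372, 5.0],
    [-41.4534, 21.5600, 5.0],
    [50.3976, -22.5455, 5.0],
    [1.9822, 21.3705, 5.0],
])
_POINTS_MIN20 = np.array([
    [20.7561, 32.8674, -5.0],
    [-26.4772, 37.2601, -5.0],
    [-43.4591, 0.0638, -5.0],
    [49.7345, -28.3946, -5.0],
    [6.2022, 42.2579, 5.0],
    [3.0729, -17.1671, 5.0],
    [31.5382, -42.3656, 5.0],
    [-41.3677, -24.5219, 5.0],
])

#: config_id -> (feature diameter mm, centroid set, modality)
_DEFAULT_CONFIGS: dict[str, tuple[float, np.ndarray, str]] = {
    "3_15": (3.0, _POINTS_MIN15, "CT"),
    "3_20": (3.0, _POINTS_MIN20, "CT"),
    "5_20": (5.0, _POINTS_MIN20, "CT"),
    "6_20": (6.0, _POINTS_MIN20, "MRI"),
}


@dataclass(frozen=True)
class ModalityProfile:
    """Modality-dependent rules used by candidate pruning.

    Candidates smaller than ``lower_volume_factor`` times the real feature
    volume are excluded for both modalities; an upper bound of
    ``upper_volume_factor`` times applies to MRI only, where bright
    artifacts of arbitrary extent are common.  Features are assumed bright
    against a darker background in both modalities.
    """

    modality: str
    lower_volume_factor: float = 0.6
    upper_volume_factor: float | None = None
    intensity_polarity: str = "bright"

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_volume_factor < 1.0:
            raise ValueError("lower_volume_factor must lie in (0, 1)")
        if self.upper_volume_factor is not None and self.upper_volume_factor <= 1.0:
            raise ValueError("upper_volume_factor must exceed 1")
        if self.intensity_polarity != "bright":
            raise ValueError("only bright fiducial features are supported")

    @classmethod
    def for_modality(cls, modality: str) -> "ModalityProfile":
        modality = modality.upper()
        if modality == "CT":
            return cls(modality="CT", lower_volume_factor=0.6, upper_volume_factor=None)
        if modality == "MRI":
            return cls(modality="MRI", lower_volume_factor=0.6, upper_volume_factor=2.0)
        raise ValueError(f"unknown modality {modality!r}")


@dataclass(frozen=True)
class MarkerGeometry:
    """Canonical description of one marker configuration.

    Attributes
    ----------
    config_id:
        Name of the configuration, e.g. ``"3_15"``.
    feature_diameter:
        Diameter of the spherical fiducial features in mm.
    feature_centroids:
        ``(8, 3)`` array of feature centroids in the marker coordinate
        system (mm).
    modality:
        Imaging modality the feature material is intended for.
    sensorholder_to_marker:
        Optional ``(4, 4)`` homogeneous matrix giving the constant pose of
        the sensor holder relative to the marker (both mount on the same
        clipping plate), used when composing tracking transform chains.
    """

    config_id: str
    feature_diameter: float
    feature_centroids: np.ndarray
    modality: str = "CT"
    sensorholder_to_marker: np.ndarray | None = None
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        pts = np.asarray(self.feature_centroids, dtype=float)
        object.__setattr__(self, "feature_centroids", pts)

    @property
    def min_distance(self) -> float:
        return float(pdist(self.feature_centroids).min())


def expected_feature_volume(geometry: MarkerGeometry) -> float:
    """Volume (mm^3) of one spherical fiducial feature, (pi/6) d^3."""
    d = geometry.feature_diameter
    if d <= 0:
        raise ValueError("feature diameter must be positive")
    return math.pi / 6.0 * d**3


def pairwise_distances(geometry: MarkerGeometry) -> np.ndarray:
    """All 28 pairwise centroid distances (mm), ascending."""
    return np.sort(pdist(geometry.feature_centroids))


def distance_signature(geometry: MarkerGeometry, index: int) -> np.ndarray:
    """Sorted distances (mm) from feature ``index`` to the seven others."""
    pts = geometry.feature_centroids
    if not 0 <= index < len(pts):
        raise IndexError(f"feature index {index} out of range 0..{len(pts) - 1}")
    d = np.linalg.norm(pts - pts[index], axis=1)
    return np.sort(d[np.arange(len(pts)) != index])


def _check_two_planes(pts: np.ndarray, tol: float) -> None:
    # First pass: smallest principal axis splits the points into the two
    # plane groups.  The groups' in-plane centroids generally differ, which
    # skews that axis, so the normal is re-estimated after removing each
    # group's mean.
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    order = np.argsort(centred @ vt[-1])
    g1, g2 = pts[order[:4]], pts[order[4:]]
    deflated = np.vstack([g1 - g1.mean(axis=0), g2 - g2.mean(axis=0)])
    _, _, vt = np.linalg.svd(deflated, full_matrices=False)
    heights = centred @ vt[-1]
    order = np.argsort(heights)
    lo, hi = heights[order[:4]], heights[order[4:]]
    if np.ptp(lo) > tol or np.ptp(hi) > tol:
        raise GeometryError(
            "feature centroids do not lie on two parallel planes "
            f"(four per plane) within {tol} mm"
        )
    if hi.min() - lo.max() <= tol:
        raise GeometryError("the two feature planes are not separated")


def validate_geometry(geometry: MarkerGeometry, tau: float | None = None) -> None:
    """Check every structural invariant of a marker geometry.

    Raises :class:`GeometryError` on the first violation: wrong feature
    count, features not on two parallel planes, or pairwise distances /
    per-feature signatures that are ambiguous at tolerance ``tau``.
    """
    tau = geometry.tau if tau is None else tau
    pts = np.asarray(geometry.feature_centroids, dtype=float)
    if pts.shape != (8, 3):
        raise GeometryError(
            f"expected 8 feature centroids with 3 coordinates, got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite feature centroid coordinates")
    if geometry.feature_diameter <= 0:
        raise GeometryError("feature diameter must be positive")

    d = np.sort(pdist(pts))
    if d[0] <= geometry.feature_diameter:
        raise GeometryError("feature spheres overlap: min centroid distance "
                            f"{d[0]:.2f} mm <= diameter")
    if np.diff(d).min() <= tau:
        raise GeometryError(
            "ambiguous geometry: two pairwise distances coincide within "
            f"tau = {tau} mm (min separation {np.diff(d).min():.3f} mm)"
        )
    # Signature uniqueness follows from distance uniqueness but is checked
    # explicitly: two features must differ in at least one signature entry.
    sigs = [distance_signature(geometry, i) for i in range(8)]
    for i, j in itertools.combinations(range(8), 2):
        if np.abs(sigs[i] - sigs[j]).max() <= tau:
            raise GeometryError(
                f"ambiguous geometry: features {i} and {j} have "
                f"indistinguishable distance signatures at tau = {tau} mm"
            )
    _check_two_planes(pts, PLANARITY_TOL)

    if geometry.sensorholder_to_marker is not None:
        m = np.asarray(geometry.sensorholder_to_marker, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError("sensorholder_to_marker must be a 4x4 matrix")


def default_geometry(config_id: str, tau: float = DEFAULT_TAU) -> MarkerGeometry:
    """One of the shipped default configurations: 3_15, 3_20, 5_20, 6_20."""
    try:
        diameter, pts, modality = _DEFAULT_CONFIGS[config_id]
    except KeyError:
        raise GeometryError(
            f"unknown configuration {config_id!r}; "
            f"available: {', '.join(sorted(_DEFAULT_CONFIGS))}"
        ) from None
    geometry = MarkerGeometry(
        config_id=config_id,
        feature_diameter=diameter,
        feature_centroids=pts.copy(),
        modality=modality,
        tau=tau,
    )
    validate_geometry(geometry)
    return geometry


def available_configs() -> tuple[str, ...]:
    return tuple(sorted(_DEFAULT_CONFIGS))


def geometry_from_mapping(data: Mapping, tau: float = DEFAULT_TAU) -> MarkerGeometry:
    """Build and validate a geometry from a parsed config mapping."""
    missing = {"id", "diameter_mm", "centroids_mm"} - set(data)
    if missing:
        raise GeometryError(f"geometry config missing fields: {sorted(missing)}")
    holder = data.get("sensorholder_to_marker")
    centroids = np.asarray(data["centroids_mm"], dtype=float)
    if centroids.ndim != 2 or centroids.shape != (8, 3):
        raise GeometryError(
            f"centroids_mm must be 8 rows of 3 values, got shape {centroids.shape}"
        )
    geometry = MarkerGeometry(
        config_id=str(data["id"]),
        feature_diameter=float(data["diameter_mm"]),
        feature_centroids=centroids,
        modality=str(data.get("modality", "CT")).upper(),
        sensorholder_to_marker=None if holder is None else np.asarray(holder, float),
        tau=tau,
    )
    validate_geometry(geometry)
    return geometry


def load_marker_geometry(path: str | Path, tau: float = DEFAULT_TAU) -> MarkerGeometry:
    """Read a marker geometry config file (YAML key-value format).

    Required fields: ``id``, ``diameter_mm``, ``centroids_mm`` (8 rows of 3).
    Optional: ``modality`` (CT|MRI, default CT), ``sensorholder_to_marker``
    (4x4 row-major, mm).  Validation failures raise :class:`GeometryError`.
    """
    path = Path(path)
    if not path.is_file():
        raise GeometryError(f"geometry config not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise GeometryError(f"geometry config {path} is not a key-value mapping")
    return geometry_from_mapping(data, tau=tau)


def save_marker_geometry(geometry: MarkerGeometry, path: str | Path) -> None:
    data = {
        "id": geometry.config_id,
        "diameter_mm": float(geometry.feature_diameter),
        "modality": geometry.modality,
        "centroids_mm": [[float(x) for x in row] for row in geometry.feature_centroids],
    }
    if geometry.sensorholder_to_marker is not None:
        data["sensorholder_to_marker"] = [
            [float(x) for x in row] for row in geometry.sensorholder_to_marker
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
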