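"""Rigid transforms, Horn's absolute orientation, and marker pose recovery.

The marker pose is the rigid transform from the marker coordinate system
into image world coordinates.  It is found in three stages:

1. *Iterative exclusion* — candidates whose pairwise distances to the other
   candidates cannot be explained by the marker's canonical distance
   configuration are removed one at a time until eight remain.
2. *Ordering* — the surviving points are assigned to geometry indices by an
   optimal one-to-one matching of per-point distance signatures.
3. *Verification* — a closed-form least-squares rigid fit (Horn's unit
   quaternion method) is computed; the fiducial registration error (FRE)
   must fall below a threshold, otherwise an exhaustive search over
   8-subsets of the most plausible candidates is attempted.

All lengths are millimetres, all angles degrees unless noted.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, FidlocError
from .marker_model import (
    MarkerGeometry,
    ModalityProfile,
    expected_feature_volume,
    pairwise_distances,
)

_ORTHO_TOL = 1e-9

#: Number of candidates retained for the exhaustive-subset fallback.
#: C(16, 8) = 12870 subsets keeps the worst case well below a second.
MAX_SUBSET_CANDIDATES = 16


class LocalizationStatus(str, Enum):
    SUCCESS = "success"
    INSUFFICIENT_CANDIDATES = "insufficient_candidates"
    NO_CONSISTENT_SUBSET = "no_consistent_subset"
    HIGH_RESIDUAL = "high_residual"


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation matrix is a reflection (det < 0)")

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_euler_degrees(
        cls, angles: Sequence[float], translation: Sequence[float] = (0, 0, 0),
        convention: str = "ZYX",
    ) -> "RigidTransform":
        rot = Rotation.from_euler(convention, angles, degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``(a.compose(b)).apply(p) == a.apply(b.apply(p))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_degrees(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(a: RigidTransform) -> RigidTransform:
    return a.invert()


def to_euler_angles(t: RigidTransform, convention: str = "ZYX") -> np.ndarray:
    """Euler angles of the rotation in degrees (intrinsic Z-Y-X by default).

    A warning is emitted near gimbal lock (middle angle within 0.1 deg of
    +-90 for the default convention), where the decomposition becomes
    ill-conditioned.
    """
    angles = Rotation.from_matrix(t.rotation).as_euler(convention, degrees=True)
    if abs(abs(angles[1]) - 90.0) < 0.1:
        warnings.warn(
            "Euler decomposition near gimbal lock; angles are ill-conditioned",
            RuntimeWarning, stacklevel=2,
        )
    return angles


def compose_chain(
    steps: Sequence[str | tuple[str, bool]],
    transforms: Mapping[str, RigidTransform],
) -> RigidTransform:
    """Compose a named chain of transforms into one rigid transform.

    ``steps`` lists transform names in the order a point passes through
    them: the first-listed transform is applied first.  A step may be given
    as ``(name, True)`` or as the string ``"~name"`` to use the inverse of
    the named transform.  A typical CT-to-US chain is::

        compose_chain(["~marker_to_ct", "~sensorholder_to_marker",
                       "sensor_to_tracker", "tracker_to_us"], registry)

    which maps CT world points into the ultrasound image frame.
    """
    result = RigidTransform.identity()
    for step in steps:
        if isinstance(step, str):
            name, inv = (step[1:], True) if step.startswith("~") else (step, False)
        else:
            name, inv = step
        if name not in transforms:
            raise KeyError(f"missing named transform {name!r}")
        t = transforms[name]
        if inv:
            t = t.invert()
        result = t.compose(result)
    return result


def horn_absolute_orientation(
    source: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Closed-form least-squares rigid fit ``target ~= R @ source + t``.

    Uses the unit-quaternion formulation: the optimal rotation is the
    eigenvector of a 4x4 symmetric matrix built from the cross-covariance
    of the centred point sets, belonging to its largest eigenvalue.  No
    scaling, no reflection.  Returns the transform and the fiducial
    registration error, the RMS of ``|R s_i + t - t_i|``.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(s)
    if n < 3:
        raise DegenerateGeometryError("at least 3 point pairs are required")

    sc, tc = s.mean(axis=0), t.mean(axis=0)
    s0, t0 = s - sc, t - tc
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are (nearly) collinear")

    m = s0.T @ t0  # cross-covariance
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    q = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(q)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    rot = Rotation.from_quat([x, y, z, w]).as_matrix()
    trans = tc - rot @ sc
    resid = s @ rot.T + trans - t
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rot, trans), fre


# ---------------------------------------------------------------------------
# Candidate-to-geometry correspondence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Outcome of candidate-to-geometry matching.

    ``order`` maps geometry feature index ``j`` to an index into the input
    candidate list; on success it is a length-8 bijection.
    """

    status: LocalizationStatus
    order: tuple[int, ...] | None = None
    transform: RigidTransform | None = None
    fre: float | None = None


def _candidate_points(candidates) -> np.ndarray:
    pts = np.asarray(
        [np.asarray(getattr(c, "centroid_world", c), float) for c in candidates]
    )
    return pts.reshape(len(candidates), 3)


def _match_scores(points: np.ndarray, canonical: np.ndarray, tau: float) -> np.ndarray:
    """Boolean N x N matrix: does distance(i, j) match any canonical distance?"""
    n = len(points)
    d = squareform(pdist(points))
    hit = (np.abs(d[..., None] - canonical[None, None, :]) <= tau).any(axis=-1)
    hit[np.diag_indices(n)] = False
    return hit


def _exclusion_order_keys(candidates, geometry: MarkerGeometry):
    """Deterministic tie-break keys for dropping a candidate: among equal
    scores, the largest |volume - V_f| drops first, then the lowest mean
    intensity, then the lowest label id.  Smaller key == dropped earlier."""
    vf = expected_feature_volume(geometry)
    keys = []
    for i, c in enumerate(candidates):
        vol = float(getattr(c, "physical_volume", vf))
        inten = float(getattr(c, "mean_intensity", 0.0))
        label = int(getattr(c, "label_id", i))
        keys.append((-abs(vol - vf), inten, label))
    return keys


def _signature_assignment(
    points: np.ndarray, geometry: MarkerGeometry
) -> tuple[np.ndarray, float]:
    """Optimal assignment of 8 points to geometry indices by distance
    signatures.  Returns ``perm`` with ``perm[j]`` = point index assigned to
    geometry feature ``j``, and the total signature discrepancy."""
    d = squareform(pdist(points))
    cand_sigs = np.sort(d, axis=1)[:, 1:]  # drop self-distance 0
    geo = geometry.feature_centroids
    dg = squareform(pdist(geo))
    geo_sigs = np.sort(dg, axis=1)[:, 1:]
    # cost[j, i]: geometry feature j vs candidate point i
    cost = np.abs(geo_sigs[:, None, :] - cand_sigs[None, :, :]).sum(axis=-1)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(8, dtype=int)
    perm[rows] = cols
    return perm, float(cost[rows, cols].sum())


def _fit_subset(
    points: np.ndarray, geometry: MarkerGeometry
) -> tuple[np.ndarray, RigidTransform, float]:
    perm, _ = _signature_assignment(points, geometry)
    transform, fre = horn_absolute_orientation(
        geometry.feature_centroids, points[perm]
    )
    return perm, transform, fre


def match_candidates_to_geometry(
    candidates: Sequence,
    geometry: MarkerGeometry,
    tau: float = 1.0,
    fre_threshold: float = 1.0,
) -> MatchResult:
    """Find the 8 candidates that are the marker's features, in order.

    ``candidates`` may be ``CandidateFeature`` objects or bare 3-vectors.
    Stage 1 scores each candidate by how many of its distances to the other
    candidates match a canonical marker distance within ``tau`` and
    iteratively drops the weakest until eight remain.  Stage 2 orders the
    survivors by distance-signature assignment; stage 3 verifies the order
    with a Horn fit.  If the residual exceeds ``fre_threshold``, all
    8-subsets of the best :data:`MAX_SUBSET_CANDIDATES` candidates are
    searched and the subset/ordering with minimal passing FRE is returned.
    """
    n = len(candidates)
    if n < 8:
        return MatchResult(LocalizationStatus.INSUFFICIENT_CANDIDATES)
    points = _candidate_points(candidates)
    canonical = pairwise_distances(geometry)
    hit = _match_scores(points, canonical, tau)
    tie_keys = _exclusion_order_keys(candidates, geometry)

    # Stage 1: iterative exclusion.  Matches depend only on point pairs, so
    # the hit matrix is computed once and rows/columns are masked out.
    alive = np.ones(n, dtype=bool)
    while alive.sum() > 8:
        scores = (hit & alive[None, :]).sum(axis=1)
        scores[~alive] = np.iinfo(scores.dtype).max
        worst = min(
            (i for i in range(n) if alive[i]),
            key=lambda i: (scores[i],) + tie_keys[i],
        )
        alive[worst] = False
    survivors = np.flatnonzero(alive)

    # Stages 2-3 on the survivors.
    perm, transform, fre = _fit_subset(points[survivors], geometry)
    if fre <= fre_threshold:
        return MatchResult(
            LocalizationStatus.SUCCESS,
            order=tuple(int(survivors[p]) for p in perm),
            transform=transform,
            fre=fre,
        )

    # Fallback: exhaustive 8-subsets of the most plausible candidates.
    if n > 8:
        final_scores = hit.sum(axis=1)
        # Keep the candidates that iterative exclusion would drop last.
        ranked = sorted(
            range(n),
            key=lambda i: (final_scores[i],) + tie_keys[i],
            reverse=True,
        )
        pool = np.array(sorted(ranked[:MAX_SUBSET_CANDIDATES]))
        best: tuple[float, tuple[int, ...], RigidTransform] | None = None
        for subset in itertools.combinations(pool, 8):
            idx = np.array(subset)
            try:
                sperm, stransform, sfre = _fit_subset(points[idx], geometry)
            except DegenerateGeometryError:
                continue
            if sfre <= fre_threshold and (best is None or sfre < best[0]):
                best = (sfre, tuple(int(idx[p]) for p in sperm), stransform)
        if best is not None:
            return MatchResult(
                LocalizationStatus.SUCCESS,
                order=best[1], transform=best[2], fre=best[0],
            )
        return MatchResult(LocalizationStatus.NO_CONSISTENT_SUBSET)
    return MatchResult(LocalizationStatus.HIGH_RESIDUAL, fre=fre)


# ---------------------------------------------------------------------------
# End-to-end localization
# ---------------------------------------------------------------------------

@dataclass
class LocalizeOptions:
    """Tunable parameters of the localization pipeline.

    ``tau`` and ``fre_threshold`` default to ``None`` meaning *derive from
    the volume*: the distance-match tolerance becomes
    ``max(1.0, 0.75 * max voxel spacing)`` and the FRE acceptance threshold
    ``max(1.0, voxel diagonal)``, since centroid error grows with slice
    thickness.
    """

    percentile: float = 0.995
    max_candidates: int = 500
    tau: float | None = None
    fre_threshold: float | None = None


@dataclass(frozen=True)
class MarkerLocalization:
    """Result of localizing a marker in one volume.

    ``transform`` maps marker coordinates to image world coordinates (mm).
    ``correspondences`` pairs each geometry feature index with the detected
    candidate chosen for it.  ``provenance`` records every threshold and
    per-stage candidate count for auditability.
    """

    status: LocalizationStatus
    transform: RigidTransform | None = None
    correspondences: tuple = ()
    fre: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.status is LocalizationStatus.SUCCESS

    def report(self) -> dict:
        """JSON-serializable localization report."""
        rep = {
            "status": self.status.value,
            "fre_mm": self.fre,
            "marker_to_image_matrix": (
                None if self.transform is None
                else [list(map(float, row)) for row in self.transform.matrix()]
            ),
            "correspondences": [
                {
                    "feature_index": int(j),
                    "centroid_world_mm": [float(x) for x in c.centroid_world],
                    "physical_volume_mm3": float(c.physical_volume),
                }
                for j, c in self.correspondences
            ],
            "parameters": dict(self.provenance),
        }
        return rep


def derive_tau(volume) -> float:
    return max(1.0, 0.75 * float(np.max(volume.spacing)))


def derive_fre_threshold(volume) -> float:
    return max(1.0, float(np.linalg.norm(volume.spacing)))


def localize_marker(
    volume,
    geometry: MarkerGeometry,
    profile: ModalityProfile | None = None,
    options: LocalizeOptions | None = None,
) -> MarkerLocalization:
    """Detect candidates, prune, match and fit: the full marker pipeline.

    Deterministic for fixed input and configuration.  Failures are reported
    through ``status``, never as silently wrong transforms.
    """
    from . import detection  # local import to avoid a cycle

    options = options or LocalizeOptions()
    profile = profile or ModalityProfile.for_modality(geometry.modality)
    tau = options.tau if options.tau is not None else derive_tau(volume)
    fre_threshold = (
        options.fre_threshold
        if options.fre_threshold is not None
        else derive_fre_threshold(volume)
    )
    provenance: dict = {
        "config_id": geometry.config_id,
        "modality": profile.modality,
        "percentile": options.percentile,
        "tau_mm": tau,
        "fre_threshold_mm": fre_threshold,
        "max_candidates": options.max_candidates,
    }

    try:
        candidates = detection.detect_candidates(
            volume, geometry, profile,
            percentile=options.percentile,
            max_candidates=options.max_candidates,
            report=provenance,
        )
    except FidlocError as exc:
        provenance["detection_error"] = str(exc)
        return MarkerLocalization(
            LocalizationStatus.INSUFFICIENT_CANDIDATES, provenance=provenance
        )

    if len(candidates) < 8:
        return MarkerLocalization(
            LocalizationStatus.INSUFFICIENT_CANDIDATES, provenance=provenance
        )

    match = match_candidates_to_geometry(
        candidates, geometry, tau=tau, fre_threshold=fre_threshold
    )
    if match.status is not LocalizationStatus.SUCCESS:
        return MarkerLocalization(match.status, fre=match.fre, provenance=provenance)
    correspondences = tuple(
        (j, candidates[ci]) for j, ci in enumerate(match.order)
    )
    return MarkerLocalization(
        LocalizationStatus.SUCCESS,
        transform=match.transform,
        correspondences=correspondences,
        fre=match.fre,
        provenance=provenance,
    )
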