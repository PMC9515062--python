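"""Assessment statistics: point prediction error, clipping precision, TRE.

The *point prediction error* (PPE) is a reference-free measure of
localization quality: a virtual target defined in the marker frame is
transformed by the six station poses of the point-symmetric assessment
phantom; with perfect localization all six transformed points coincide, so
their RMS spread about their mean quantifies the localization error at the
target's distance:

    PPE = sqrt( sum_i |p_i - p_bar|^2 / 6 ),   p_bar = mean(p_1..p_6).

The *repeatability error* applies the identical formula to six repeat
scans of one fixed pose.  The *clipping precision* summarizes the pose
dispersion of a remountable sensor holder over repeated clip-on events,
as the mean absolute deviation of the scalar sensor distances
(translational) and the mean L2 deviation of the Euler-angle vectors
(rotational).  The *target registration error* (TRE) is the Euclidean
distance between a registered target position and its independently
marked reference.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .pose import RigidTransform


@dataclass(frozen=True)
class PoseSeries:
    """An ordered series of marker poses (station series or repeat scans)."""

    transforms: tuple[RigidTransform, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "transforms", tuple(self.transforms))
        if len(self.transforms) < 2:
            raise ValueError("a pose series needs at least 2 entries")
        if self.labels and len(self.labels) != len(self.transforms):
            raise ValueError("labels must match transforms in length")


def _transforms(series) -> tuple[RigidTransform, ...]:
    if isinstance(series, PoseSeries):
        return series.transforms
    return tuple(series)


def point_dispersion_rms(series, target) -> float:
    """RMS spread of a marker-frame target under a series of poses (any n)."""
    transforms = _transforms(series)
    if len(transforms) < 2:
        raise ValueError("need at least 2 transforms")
    target = np.asarray(target, dtype=float).reshape(3)
    if not np.all(np.isfinite(target)):
        raise ValueError("target must be finite")
    pts = np.array([t.apply(target) for t in transforms])
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def point_prediction_error(series, target) -> float:
    """PPE of a virtual target under the six station poses (mm).

    Requires exactly six transforms, matching the six point-symmetric
    docking stations the statistic is defined for; use
    :func:`point_dispersion_rms` for other series lengths.
    """
    transforms = _transforms(series)
    if len(transforms) != 6:
        raise ValueError(
            f"PPE is defined over exactly 6 poses, got {len(transforms)}; "
            "use point_dispersion_rms for a generalized series"
        )
    return point_dispersion_rms(transforms, target)


def repeatability_error(series, target) -> float:
    """PPE formula applied to six successive scans of one fixed pose (mm)."""
    transforms = _transforms(series)
    if len(transforms) != 6:
        raise ValueError("repeatability error is defined over exactly 6 repeats")
    return point_dispersion_rms(transforms, target)


# ---------------------------------------------------------------------------
# Clipping precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClippingSeries:
    """Repeated clip-on measurements of the sensor holder pose.

    ``distances`` holds the scalar distance |l_i| (mm) between the
    reference sensor and the sensor holder for each clip-on event;
    ``euler_vectors`` the corresponding Euler-angle 3-vectors (degrees) of
    the relative orientation.
    """

    distances: np.ndarray
    euler_vectors: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float).reshape(-1)
        e = np.asarray(self.euler_vectors, dtype=float).reshape(-1, 3)
        if len(d) != len(e):
            raise ValueError("distances and euler_vectors must have equal length")
        if len(d) < 2:
            raise ValueError("a clipping series needs at least 2 samples")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "euler_vectors", e)


def _distances(series) -> np.ndarray:
    if isinstance(series, ClippingSeries):
        return series.distances
    return np.asarray(series, dtype=float).reshape(-1)


def _eulers(series) -> np.ndarray:
    if isinstance(series, ClippingSeries):
        return series.euler_vectors
    return np.asarray(series, dtype=float).reshape(-1, 3)


def clipping_translation_precision(series) -> float:
    """Mean absolute deviation of the scalar distances l_i from their mean.

    This is the literal scalar form: it uses the distance magnitudes only
    and is therefore blind to tangential shifts of the sensor holder; see
    :func:`translation_dispersion_vector` for the vector-based variant.
    """
    l = _distances(series)
    if len(l) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.abs(l - l.mean())))


def translation_dispersion_vector(positions) -> float:
    """Vector-based alternative: mean L2 deviation of the 3D sensor-holder
    positions from their mean position (mm)."""
    p = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(p) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.linalg.norm(p - p.mean(axis=0), axis=1)))


def unwrap_euler_degrees(euler_vectors) -> np.ndarray:
    """Unwrap Euler-angle samples component-wise relative to the first
    sample, removing +-360 deg jumps so that means are well defined."""
    e = np.asarray(euler_vectors, dtype=float).reshape(-1, 3).copy()
    ref = e[0]
    e -= np.round((e - ref) / 360.0) * 360.0
    return e


def clipping_rotation_precision(series) -> float:
    """Mean L2 deviation of the Euler-angle vectors from their mean (deg).

    Samples must be unwrapped (no +-180 deg jumps); a component range above
    180 deg raises, instructing the caller to unwrap first (see
    :func:`unwrap_euler_degrees`).
    """
    e = _eulers(series)
    if len(e) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(e, axis=0).max() > 180.0:
        raise ValueError(
            "euler angle samples span more than 180 deg; unwrap them first "
            "(unwrap_euler_degrees) so the component-wise mean is meaningful"
        )
    dev = e - e.mean(axis=0)
    return float(np.mean(np.linalg.norm(dev, axis=1)))


# ---------------------------------------------------------------------------
# Target registration error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TREResult:
    per_target: np.ndarray
    mean: float
    sd: float

    def __iter__(self):
        return iter(self.per_target)


def target_registration_error(registered, reference) -> TREResult:
    """Per-target Euclidean errors plus mean and sample (n-1) sd (mm)."""
    r = np.asarray(registered, dtype=float).reshape(-1, 3)
    m = np.asarray(reference, dtype=float).reshape(-1, 3)
    if r.shape != m.shape or len(r) < 1:
        raise ValueError("registered and reference must be matching (n, 3) sets")
    tre = np.linalg.norm(r - m, axis=1)
    sd = float(np.std(tre, ddof=1)) if len(tre) > 1 else float("nan")
    return TREResult(per_target=tre, mean=float(tre.mean()), sd=sd)
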