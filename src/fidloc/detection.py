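"""Reduction of a volume to bright-sphere candidate features.

The pipeline is self-adjusting in the sense that every threshold is derived
from the image at hand rather than fixed in intensity units:

1. *Background suppression* — an intensity cutoff at a high percentile of
   the voxel intensities, combined with a modality floor (300 HU for
   CT-like intensity ranges), removes soft-tissue-level signal.
2. *Edge response* — spherical features of diameter ``d`` produce a strong
   smoothed-gradient shell; the derivative scale is ``d / 6`` mm and
   respects anisotropic voxel spacing.
3. *Binarization and labelling* — an automatic two-class (Otsu) threshold
   on the nonzero edge responses yields closed shells; shells are filled,
   intersected with the intensity mask, hole-filled and labelled with
   26-connectivity.  Each connected component becomes a candidate with an
   intensity-weighted world centroid.
4. *Volume pruning* — candidates smaller than 0.6 times the real feature
   volume (CT and MRI), or larger than 2 times it (MRI only), are excluded.

Components touching the volume boundary are discarded: a feature must be
completely captured to be localizable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import NoForegroundError, NoisyVolumeError
from .marker_model import MarkerGeometry, ModalityProfile, expected_feature_volume
from .volume_io import Volume

logger = logging.getLogger(__name__)

#: Modality intensity floor applied when the volume looks HU-calibrated
#: (contains air-like values well below 0).
CT_HU_FLOOR = 300.0
_HU_AIR_CUTOFF = -200.0


@dataclass(frozen=True)
class CandidateFeature:
    """One connected bright component.

    ``physical_volume`` is ``voxel_count`` times the voxel volume;
    ``centroid_world`` is the intensity-weighted mean of the component's
    voxel world positions (mm).
    """

    centroid_world: np.ndarray
    physical_volume: float
    voxel_count: int
    mean_intensity: float
    label_id: int
    centroid_voxel: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centroid_world", np.asarray(self.centroid_world, float).reshape(3)
        )
        if self.voxel_count < 1:
            raise ValueError("a candidate must contain at least one voxel")


class SuppressionResult(NamedTuple):
    volume: Volume
    threshold: float


def suppress_background(
    volume: Volume, profile: ModalityProfile, percentile: float = 0.995
) -> SuppressionResult:
    """Set voxels at or below an automatic intensity threshold to the minimum.

    The threshold is the larger of the ``percentile`` intensity quantile
    and the modality floor (CT: 300 HU, applied only when the intensity
    range looks HU-calibrated).  Voxels strictly above the threshold
    survive.  The chosen threshold is returned alongside the volume.
    """
    vox = np.asarray(volume.voxels, dtype=float)
    vmin = float(vox.min())
    if vox.max() == vmin:
        raise NoForegroundError("constant-intensity volume: no foreground")
    threshold = float(np.quantile(vox, percentile))
    if profile.modality == "CT" and vmin <= _HU_AIR_CUTOFF:
        threshold = max(threshold, CT_HU_FLOOR)
    out = vox.copy()
    out[out <= threshold] = vmin
    if not np.any(out > vmin):
        raise NoForegroundError(
            f"no voxels above the automatic threshold {threshold:.1f}"
        )
    suppressed = Volume(
        voxels=out, spacing=volume.spacing, origin=volume.origin,
        direction=volume.direction, modality_hint=volume.modality_hint,
    )
    return SuppressionResult(suppressed, threshold)


def edge_response(volume: Volume, feature_diameter: float) -> Volume:
    """Smoothed-gradient magnitude tuned to a sphere of the given diameter.

    The Gaussian derivative scale is ``feature_diameter / 6`` in mm; each
    axis uses its own sigma in voxel units so anisotropic grids respond
    isotropically in physical space.  The response is linear in the input
    intensities and peaks on a shell at roughly the sphere radius.
    """
    sigma_mm = feature_diameter / 6.0
    vox = np.asarray(volume.voxels, dtype=float)
    sx, sy, sz = volume.spacing
    sigmas_zyx = (sigma_mm / sz, sigma_mm / sy, sigma_mm / sx)
    spac_zyx = (sz, sy, sx)
    sq = np.zeros_like(vox)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 1
        g = ndimage.gaussian_filter(vox, sigma=sigmas_zyx, order=tuple(order))
        sq += (g / spac_zyx[axis]) ** 2
    return Volume(
        voxels=np.sqrt(sq), spacing=volume.spacing, origin=volume.origin,
        direction=volume.direction, modality_hint=volume.modality_hint,
    )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def binarize_and_label(
    suppressed: Volume,
    edges: Volume,
    max_candidates: int = 500,
    min_voxels: int = 1,
) -> tuple[np.ndarray, list[CandidateFeature]]:
    """Binarize the filtered volume and extract candidate components.

    Foreground voxels must pass the intensity mask (survivors of
    background suppression) and lie inside a filled edge shell; interiors
    that fell below the intensity cutoff are closed by hole filling.
    Connected components (26-connectivity) become
    :class:`CandidateFeature` entries with intensity-weighted world
    centroids.  Components touching the volume boundary are discarded, as
    are components below ``min_voxels`` voxels — callers set this to the
    voxel count below which the volume-pruning rule would reject the
    component anyway, which keeps isolated noise voxels from exhausting
    the component budget.
    """
    if suppressed.voxels.shape != edges.voxels.shape:
        raise ValueError("suppressed and edge volumes must share one grid")
    vox = np.asarray(suppressed.voxels, dtype=float)
    vmin = vox.min()
    intensity_mask = vox > vmin

    edge_vals = np.asarray(edges.voxels, dtype=float)
    positive = edge_vals[edge_vals > 0]
    if positive.size and positive.max() > positive.min():
        cut = threshold_otsu(positive)
        shell = edge_vals > cut
        objects = ndimage.binary_fill_holes(shell)
    else:
        objects = np.ones_like(intensity_mask)

    mask = ndimage.binary_fill_holes(intensity_mask & objects)
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n and min_voxels > 1:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_voxels
        keep[0] = True
        if not keep.all():
            mask &= keep[labels]
            labels, n = ndimage.label(mask, structure=_CONN26)
    if n > max_candidates:
        raise NoisyVolumeError(
            f"{n} components exceed the limit of {max_candidates}; "
            "raise the suppression percentile or the candidate limit"
        )
    if n == 0:
        return labels, []

    weights = vox - vmin
    counts = np.bincount(labels.ravel())[1:]
    wsums = ndimage.sum_labels(weights, labels, index=np.arange(1, n + 1))
    vsums = ndimage.sum_labels(vox, labels, index=np.arange(1, n + 1))

    nz, ny, nx = labels.shape
    candidates: list[CandidateFeature] = []
    voxel_volume = suppressed.voxel_volume
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        # boundary contact check
        if (
            sl[0].start == 0 or sl[0].stop == nz
            or sl[1].start == 0 or sl[1].stop == ny
            or sl[2].start == 0 or sl[2].stop == nx
        ):
            continue
        sub = labels[sl] == lab
        w = weights[sl][sub]
        zz, yy, xx = np.nonzero(sub)
        coords = np.column_stack([
            xx + sl[2].start, yy + sl[1].start, zz + sl[0].start
        ]).astype(float)
        if w.sum() > 0:
            cv = (coords * w[:, None]).sum(axis=0) / w.sum()
        else:
            cv = coords.mean(axis=0)
        candidates.append(
            CandidateFeature(
                centroid_world=suppressed.voxel_to_world(cv),
                physical_volume=float(counts[lab - 1]) * voxel_volume,
                voxel_count=int(counts[lab - 1]),
                mean_intensity=float(vsums[lab - 1] / counts[lab - 1]),
                label_id=lab,
                centroid_voxel=cv,
            )
        )
    return labels, candidates


def prune_candidates_by_volume(
    candidates: Sequence[CandidateFeature],
    geometry: MarkerGeometry,
    profile: ModalityProfile,
) -> list[CandidateFeature]:
    """Exclude candidates implausibly small (CT and MRI) or large (MRI).

    Keeps candidates with physical volume at least
    ``lower_volume_factor * V_f`` and — when the profile defines an upper
    factor — at most ``upper_volume_factor * V_f``, where ``V_f`` is the
    real fiducial feature volume.
    """
    vf = expected_feature_volume(geometry)
    lo = profile.lower_volume_factor * vf
    hi = (
        profile.upper_volume_factor * vf
        if profile.upper_volume_factor is not None
        else np.inf
    )
    return [c for c in candidates if lo <= c.physical_volume <= hi]


def detect_candidates(
    volume: Volume,
    geometry: MarkerGeometry,
    profile: ModalityProfile | None = None,
    percentile: float = 0.995,
    max_candidates: int = 500,
    report: dict | None = None,
) -> list[CandidateFeature]:
    """Run the full candidate pipeline and return pruned candidates.

    Deterministic for fixed input and configuration.  Per-stage counts and
    the chosen intensity threshold are logged and, when a ``report`` dict
    is supplied, recorded there for auditability.
    """
    profile = profile or ModalityProfile.for_modality(geometry.modality)
    suppressed, threshold = suppress_background(volume, profile, percentile)
    edges = edge_response(suppressed, geometry.feature_diameter)
    # components this small can never pass the lower volume-pruning bound
    min_voxels = max(1, math.ceil(
        profile.lower_volume_factor * expected_feature_volume(geometry)
        / volume.voxel_volume
    ))
    _, raw = binarize_and_label(
        suppressed, edges, max_candidates=max_candidates, min_voxels=min_voxels
    )
    pruned = prune_candidates_by_volume(raw, geometry, profile)
    logger.info(
        "detection: threshold=%.2f, components=%d, after volume pruning=%d",
        threshold, len(raw), len(pruned),
    )
    if report is not None:
        report.update(
            intensity_threshold=threshold,
            n_components=len(raw),
            n_after_volume_pruning=len(pruned),
        )
    return pruned
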