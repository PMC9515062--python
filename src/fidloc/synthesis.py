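"""Ground-truthed synthetic volumes and assessment-phantom series.

The generator emulates the measurement setup used to assess marker
localization: bright spherical features on a low-intensity background,
rendered onto anisotropic voxel grids with exact partial-volume fractions
(supersampled occupancy), optional Gaussian noise, smoothing and a
multiplicative bias field, plus an assessment phantom with six docking
stations placed point-symmetrically at 100 mm around a symmetry point.

The six ground-truth station poses are generated by rotating one base pose
about the phantom's symmetry axis, so every virtual target point on that
axis maps to a single common world point under all six ideal poses — the
ideal point prediction error is exactly zero by construction, and any
measured PPE is attributable to the localization algorithm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import RenderError
from .marker_model import MarkerGeometry
from .pose import RigidTransform
from .volume_io import Volume

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class RenderProfile:
    """Appearance parameters of a rendered scan.

    Defaults emulate a CT of steel features: HU-like background 40,
    feature plateau 3000, additive Gaussian noise sigma 15.  For MRI use
    :func:`mri_profile` (lower contrast, more noise, optional bias field).
    ``supersampling`` subdivides each voxel per axis when computing sphere
    occupancy; 4 bounds the per-voxel fraction error by 1/64.
    """

    feature_intensity: float = 3000.0
    background_intensity: float = 40.0
    noise_sd: float = 15.0
    blur_fwhm: float = 0.0
    bias_field_amplitude: float = 0.0
    supersampling: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_intensity <= self.background_intensity:
            raise ValueError("feature contrast must be positive")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")

    @property
    def contrast(self) -> float:
        return self.feature_intensity - self.background_intensity


def ct_profile(noise_sd: float = 15.0, seed: int = 0, **kw) -> RenderProfile:
    return RenderProfile(feature_intensity=3000.0, background_intensity=40.0,
                         noise_sd=noise_sd, seed=seed, **kw)


def mri_profile(noise_sd: float = 20.0, seed: int = 0,
                bias_field_amplitude: float = 0.0, **kw) -> RenderProfile:
    return RenderProfile(feature_intensity=1000.0, background_intensity=100.0,
                         noise_sd=noise_sd, seed=seed,
                         bias_field_amplitude=bias_field_amplitude, **kw)


def _subvoxel_offsets(supersampling: int, spacing: np.ndarray) -> np.ndarray:
    """World-space offsets (mm) of the supersampling points of one voxel."""
    s = supersampling
    centres = (np.arange(s) + 0.5) / s - 0.5
    ox, oy, oz = np.meshgrid(centres, centres, centres, indexing="ij")
    off = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    return off * spacing


def _add_ellipsoid(
    volume: Volume,
    center_world: np.ndarray,
    semiaxes: np.ndarray,
    amplitude: float,
    supersampling: int,
) -> None:
    """Add ``amplitude * occupancy`` of an axis-aligned ellipsoid in place."""
    spacing = volume.spacing
    nz, ny, nx = volume.voxels.shape
    cv = volume.world_to_voxel(center_world)
    half = semiaxes / spacing + 1.0
    lo = np.maximum(np.floor(cv - half).astype(int), 0)
    hi = np.minimum(np.ceil(cv + half).astype(int) + 1, [nx, ny, nz])
    if np.any(lo >= hi):
        return
    ix = np.arange(lo[0], hi[0])
    iy = np.arange(lo[1], hi[1])
    iz = np.arange(lo[2], hi[2])
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    idx = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    centres = volume.voxel_to_world(idx)
    off = _subvoxel_offsets(supersampling, spacing)
    rel = (centres[:, None, :] + off[None, :, :] - center_world) / semiaxes
    inside = (rel**2).sum(axis=-1) <= 1.0
    frac = inside.mean(axis=1)
    volume.voxels[gz.ravel(), gy.ravel(), gx.ravel()] += amplitude * frac


def _bias_field(shape_zyx: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * f, |f| <= 1 (low-order
    random polynomial over normalized coordinates)."""
    nz, ny, nx = shape_zyx
    z, y, x = np.meshgrid(
        np.linspace(-1, 1, nz), np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
        indexing="ij",
    )
    coeff = rng.uniform(-1, 1, size=7)
    f = (coeff[0] + coeff[1] * x + coeff[2] * y + coeff[3] * z
         + coeff[4] * x * y + coeff[5] * y * z + coeff[6] * x * z)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def render_marker_volume(
    geometry: MarkerGeometry,
    pose: RigidTransform,
    profile: RenderProfile,
    spacing=(0.98, 0.98, 1.0),
    extent: tuple[np.ndarray, np.ndarray] | None = None,
    margin: float = 12.0,
) -> tuple[Volume, RigidTransform]:
    """Render one scan of the marker at the given pose.

    ``extent`` is an optional pair (world min corner, world max corner);
    by default the grid is fitted around the transformed features plus
    ``margin`` mm.  Every feature must lie completely inside the extent.
    Each voxel receives ``background + contrast * occupancy`` where the
    occupancy is the supersampled sphere partial-volume fraction, followed
    by optional blur, bias field and additive Gaussian noise drawn from
    ``profile.seed``.  Returns the volume and the ground-truth pose.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise RenderError("spacing must be strictly positive")
    centres = pose.apply(geometry.feature_centroids)
    r = geometry.feature_diameter / 2.0
    if extent is None:
        lo = centres.min(axis=0) - r - margin
        hi = centres.max(axis=0) + r + margin
    else:
        lo = np.asarray(extent[0], float)
        hi = np.asarray(extent[1], float)
        if np.any(centres - r < lo) or np.any(centres + r > hi):
            raise RenderError("a fiducial feature is truncated by the extent")
    shape_xyz = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo + spacing / 2.0
    nx, ny, nz = shape_xyz
    volume = Volume(
        voxels=np.full((nz, ny, nx), profile.background_intensity, dtype=float),
        spacing=spacing,
        origin=origin,
        modality_hint="CT" if geometry.modality == "CT" else "MRI",
    )
    semiaxes = np.full(3, r)
    for c in centres:
        _add_ellipsoid(volume, c, semiaxes, profile.contrast, profile.supersampling)

    rng = np.random.default_rng(profile.seed)
    if profile.blur_fwhm > 0:
        sigma_mm = profile.blur_fwhm * _FWHM_TO_SIGMA
        sz, sy, sx = spacing[2], spacing[1], spacing[0]
        volume.voxels[:] = ndimage.gaussian_filter(
            volume.voxels, sigma=(sigma_mm / sz, sigma_mm / sy, sigma_mm / sx)
        )
    if profile.bias_field_amplitude > 0:
        volume.voxels *= _bias_field(
            volume.voxels.shape, profile.bias_field_amplitude, rng
        )
    if profile.noise_sd > 0:
        volume.voxels += rng.normal(0.0, profile.noise_sd, size=volume.voxels.shape)
    return volume, pose


# ---------------------------------------------------------------------------
# Assessment phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the six-station assessment phantom.

    Stations sit evenly on a circle of ``station_radius`` mm around the
    symmetry point, in the z = const plane of the phantom frame; stations
    i and i + n/2 are antipodal.  The *plane* phantom mounts the marker
    flat; the *angle* phantom tilts it by ``tilt_deg`` toward the symmetry
    point.  ``target_distances`` are distances (mm) along the symmetry
    axis at which virtual target points are placed; the 100 mm target is
    always present for comparability between phantoms.
    """

    kind: str = "plane"
    station_radius: float = 100.0
    n_stations: int = 6
    tilt_deg: float = 0.0
    symmetry_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_distances: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0, 150.0, 175.0)

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "angle"):
            raise ValueError("kind must be 'plane' or 'angle'")
        if self.kind == "plane" and self.tilt_deg != 0.0:
            raise ValueError("plane phantom mounts the marker flat (tilt 0)")
        if self.station_radius <= 0:
            raise ValueError("station radius must be positive")
        if self.n_stations < 2 or self.n_stations % 2:
            raise ValueError(
                "stations must be point-symmetric: n_stations even and >= 2"
            )
        if 100.0 not in self.target_distances:
            raise ValueError("the 100 mm virtual target is always included")

    @classmethod
    def plane(cls, **kw) -> "PhantomSpec":
        return cls(kind="plane", tilt_deg=0.0, **kw)

    @classmethod
    def angle(cls, tilt_deg: float = 30.0, **kw) -> "PhantomSpec":
        if kw.pop("kind", "angle") != "angle":
            raise ValueError("use PhantomSpec.plane for the planar phantom")
        return cls(kind="angle", tilt_deg=tilt_deg, **kw)

    def station_positions(self) -> np.ndarray:
        c = np.asarray(self.symmetry_point, float)
        ang = 2.0 * np.pi * np.arange(self.n_stations) / self.n_stations
        return c + self.station_radius * np.column_stack(
            [np.cos(ang), np.sin(ang), np.zeros_like(ang)]
        )

    def target_label(self, distance: float) -> str:
        return f"P-{distance:g}"


@dataclass(frozen=True)
class PhantomSeries:
    """Rendered phantom series with its ground truth."""

    spec: PhantomSpec
    geometry: MarkerGeometry
    volumes: tuple[Volume, ...]
    transforms: tuple[RigidTransform, ...]
    #: label -> virtual target point in the *marker* coordinate system (mm)
    virtual_targets: dict[str, np.ndarray]
    #: label -> the common world point every ideal pose maps the target to
    target_world: dict[str, np.ndarray]


def ground_truth_transforms(spec: PhantomSpec) -> list[RigidTransform]:
    """Ideal marker->world pose at each docking station.

    The base pose places the marker at station 0, its feature planes
    parallel to the station plane (tilted toward the symmetry point by
    ``tilt_deg`` for the angle phantom); poses 1..n-1 are rotations of the
    base pose about the symmetry axis.
    """
    c = np.asarray(spec.symmetry_point, float)
    stations = spec.station_positions()
    # Tilt about the tangential (y) axis at station 0 leans the marker
    # normal toward the symmetry point.
    base = RigidTransform.from_euler_degrees(
        (0.0, spec.tilt_deg, 0.0), stations[0], convention="ZYX"
    )
    out = []
    for i in range(spec.n_stations):
        ang = 360.0 * i / spec.n_stations
        rotz = RigidTransform.from_euler_degrees((ang, 0, 0), (0, 0, 0))
        about_c = RigidTransform(rotz.rotation, c - rotz.rotation @ c)
        out.append(about_c.compose(base))
    return out


def virtual_targets_marker_cs(
    spec: PhantomSpec,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Virtual target points, in marker coordinates and in world coordinates.

    Targets lie on the symmetry axis at the configured distances from the
    symmetry point; expressed in the marker frame through the base pose,
    every ideal station pose maps them back onto the axis point.
    """
    c = np.asarray(spec.symmetry_point, float)
    base = ground_truth_transforms(spec)[0]
    inv = base.invert()
    marker_cs, world = {}, {}
    for dist in spec.target_distances:
        label = spec.target_label(dist)
        p_world = c + np.array([0.0, 0.0, dist])
        marker_cs[label] = inv.apply(p_world)
        world[label] = p_world
    return marker_cs, world


def make_phantom_series(
    spec: PhantomSpec,
    geometry: MarkerGeometry,
    profile: RenderProfile,
    spacing=(0.98, 0.98, 1.0),
) -> PhantomSeries:
    """Render one volume per docking station with known ground truth.

    Station ``i`` is rendered with seed ``profile.seed + i`` so the series
    is reproducible while the noise is independent across stations.
    """
    transforms = ground_truth_transforms(spec)
    marker_targets, world_targets = virtual_targets_marker_cs(spec)
    volumes = []
    for i, t in enumerate(transforms):
        station_profile = dataclasses.replace(profile, seed=profile.seed + i)
        vol, _ = render_marker_volume(geometry, t, station_profile, spacing=spacing)
        volumes.append(vol)
    return PhantomSeries(
        spec=spec,
        geometry=geometry,
        volumes=tuple(volumes),
        transforms=tuple(transforms),
        virtual_targets=marker_targets,
        target_world=world_targets,
    )


def inject_distractors(
    volume: Volume,
    n: int,
    diameter_range: tuple[float, float],
    intensity_range: tuple[float, float],
    seed: int,
    avoid_points=(),
    clearance: float | None = None,
    supersampling: int = 4,
) -> Volume:
    """Add ``n`` bright ellipsoidal distractor blobs at random positions.

    Blob positions are drawn uniformly inside the volume (keeping the blob
    fully interior) and rejected while closer than ``clearance`` mm
    (default: twice the largest blob diameter) to any point in
    ``avoid_points`` — typically the true feature centroids — or to a
    previously placed blob.  Intensities are the added contrast above the
    local background.  Placement is reproducible by ``seed``; if a blob
    cannot be placed in 1000 tries a :class:`RenderError` is raised.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    out = Volume(
        voxels=volume.voxels.copy(), spacing=volume.spacing,
        origin=volume.origin, direction=volume.direction,
        modality_hint=volume.modality_hint,
    )
    if n == 0:
        return out
    rng = np.random.default_rng(seed)
    dmin, dmax = diameter_range
    if clearance is None:
        clearance = 2.0 * dmax
    avoid = [np.asarray(p, float) for p in avoid_points]
    nx, ny, nz = out.shape_xyz
    world_lo = out.voxel_to_world((0, 0, 0)) - out.spacing / 2
    world_hi = out.voxel_to_world((nx - 1, ny - 1, nz - 1)) + out.spacing / 2
    for _ in range(n):
        for attempt in range(1000):
            d = rng.uniform(dmin, dmax)
            semi = 0.5 * d * rng.uniform(0.8, 1.25, size=3)
            margin = semi.max() + out.spacing
            centre = rng.uniform(world_lo + margin, world_hi - margin)
            if avoid and min(np.linalg.norm(centre - p) for p in avoid) < clearance:
                continue
            break
        else:
            raise RenderError(
                "could not place a distractor blob without overlap in 1000 tries"
            )
        amplitude = rng.uniform(*intensity_range)
        _add_ellipsoid(out, centre, semi, amplitude, supersampling)
        avoid.append(centre)
    return out


def reslice(volume: Volume, new_thickness: float) -> Volume:
    """Slab-average along z to emulate a thick-slice reconstruction.

    Slice thickness and slice spacing of the output both equal
    ``new_thickness``.  Slab boundaries are taken at the nearest input
    slice boundary when the thickness ratio is not an integer.  World
    extent is preserved to within one slab.
    """
    sz = float(volume.spacing[2])
    if new_thickness < sz - 1e-9:
        raise ValueError("new thickness must be >= the original z spacing")
    ratio = new_thickness / sz
    if abs(ratio - 1.0) < 1e-9:
        return Volume(
            voxels=volume.voxels.copy(), spacing=volume.spacing,
            origin=volume.origin, direction=volume.direction,
            modality_hint=volume.modality_hint,
        )
    nz = volume.voxels.shape[0]
    n_new = int(nz / ratio)
    if n_new < 1:
        raise ValueError("volume thinner than one output slab")
    bounds = np.round(np.arange(n_new + 1) * ratio).astype(int)
    slabs = [
        volume.voxels[bounds[k]:max(bounds[k + 1], bounds[k] + 1)].mean(axis=0)
        for k in range(n_new)
    ]
    new_spacing = volume.spacing.copy()
    new_spacing[2] = new_thickness
    # first output voxel centre sits half a slab into the old grid
    new_origin = volume.origin + volume.direction @ np.array(
        [0.0, 0.0, (new_thickness - sz) / 2.0]
    )
    return Volume(
        voxels=np.stack(slabs), spacing=new_spacing, origin=new_origin,
        direction=volume.direction, modality_hint=volume.modality_hint,
    )
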