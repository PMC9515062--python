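# Methods

This note documents the models, algorithms and numerical choices behind
`fidloc`, and what the synthetic evaluation does and does not demonstrate.

## Marker model

A marker carries eight spherical fiducial features distributed over two
parallel planes, four per plane. Configurations are named
`<diameter>_<min distance>` (mm): `3_15`, `3_20`, `5_20` (CT, steel-like
features) and `6_20` (MRI-visible features). Correspondence between
detected candidates and canonical features is established purely from
pairwise distances, which requires the distance configuration to be
unambiguous: the package validates that all 28 pairwise distances, and
consequently all eight per-feature distance signatures (the sorted
7-vector of distances to the other features), are mutually separated by
more than a tolerance τ.

**τ (uniqueness/matching tolerance), default 1.0 mm.** Matching compares
measured centroid distances against canonical ones, so the geometry's
ambiguity scale must exceed the centroid estimation error (roughly one
in-plane voxel at ≈ 1 mm). During localization the matching tolerance is
additionally widened with slice thickness, `max(1.0, 0.75 · max spacing)`
mm, because centroid error grows with slab height.

**Shipped default coordinates.** Pairwise-distance uniqueness at
τ = 1.0 mm forces the largest pairwise distance to be at least
min-distance + 27 · τ, i.e. a fairly large device. The shipped coordinate
sets were found by penalty optimization (minimum distance exactly
15 / 20 mm, planes 10 mm apart, all distance gaps > 1.5 mm, overall span
≈ 100 mm) and are configuration data, not constants of the algorithm:
any user geometry satisfying the invariants can be supplied as a YAML
file (`id`, `diameter_mm`, `modality`, `centroids_mm`, optional
`sensorholder_to_marker`).

## Localization pipeline

All stages derive their thresholds from the image at hand.

1. **Background suppression.** Threshold = max(intensity quantile at
   percentile *p* (default 0.995), modality floor). The floor is 300 HU
   for CT and only applies when the intensity range looks HU-calibrated
   (minimum ≤ −200, i.e. air present); synthetic or rescaled volumes are
   handled by the quantile alone. Voxels at or below the threshold are
   set to the volume minimum; a constant volume is an error.
2. **Edge response.** Smoothed gradient magnitude with Gaussian
   derivative scale σ = d/6 mm (d = feature diameter), converted to
   per-axis voxel sigmas so anisotropic grids respond isotropically in
   physical space. The response is linear in intensity and peaks on a
   shell at radius ≈ d/2.
3. **Binarization and labelling.** The positive edge responses are split
   by Otsu's threshold; filled edge shells define object regions, which
   are intersected with the intensity mask and hole-filled. Connected
   components (26-connectivity) yield candidates with intensity-weighted
   world centroids (weights = suppressed intensity above the floor,
   giving sub-voxel accuracy). Components touching the volume boundary
   are discarded (a feature must be completely captured), and components
   smaller than the volume-pruning lower bound are dropped early so that
   isolated noise voxels cannot exhaust the component budget
   (`max_candidates`, default 500).
4. **Volume pruning.** Keep candidates with physical volume
   ≥ 0.6 · V_f; for MRI additionally ≤ 2 · V_f, with V_f = (π/6) d³.
   The measured component volume is the full above-threshold support and
   therefore systematically exceeds the geometric sphere volume by a
   partial-volume margin; the 0.6/2.0 factors leave room for this at
   clinical voxel sizes.
5. **Matching.** Stage 1 scores each candidate by how many of its
   distances to the other candidates match *any* canonical distance
   within τ, and iteratively removes the weakest candidate until eight
   remain (deterministic tie-breaks: larger |volume − V_f| drops first,
   then lower mean intensity, then lower label id). Stage 2 assigns the
   surviving eight points to geometry indices by minimizing total
   distance-signature discrepancy (Hungarian assignment on L1 signature
   costs). Stage 3 fits the pose and verifies it.
6. **Pose fit.** Horn's closed-form unit-quaternion absolute
   orientation: the optimal rotation is the eigenvector to the largest
   eigenvalue of the 4×4 matrix built from the cross-covariance of the
   centred point sets; no scaling, no reflection. The fiducial
   registration error (FRE) is the RMS residual. A localization is
   accepted only if FRE ≤ `max(1.0 mm, voxel diagonal)`; otherwise all
   8-subsets of the 16 most plausible candidates (12 870 combinations,
   well under a second) are searched and the passing subset with minimal
   FRE is returned. If nothing passes, the result status is
   `no_consistent_subset` — the pipeline never returns a silently wrong
   pose, which the distractor and missing-feature tests verify.

Euler angles use the intrinsic Z-Y-X convention in degrees (configurable);
the decomposition warns near gimbal lock. Transform chains
(e.g. CT → marker → sensor holder → tracker → US) are composed from a
named registry with per-step inversion flags.

## Assessment statistics

* **PPE**: RMS spread √(Σᵢ₌₁⁶ ‖pᵢ − p̄‖²/6) of a marker-frame virtual
  target mapped by the six station poses; defined for exactly six poses
  (the generalized-n variant is `point_dispersion_rms`).
* **Repeatability error**: same formula over six repeat scans of one pose.
* **Clipping precision**: ε_trans = mean |lᵢ − l_mean| over the scalar
  sensor distances — implemented literally, and therefore blind to
  tangential shifts; a clearly named vector-based alternative
  (`translation_dispersion_vector`) is provided. ε_rot = mean
  ‖θᵢ − θ_mean‖₂ over Euler-angle vectors, with samples unwrapped
  relative to the first sample before averaging (component ranges above
  180° are rejected with instructions to unwrap).
* **TRE**: per-target Euclidean distances, summarized as mean ± sample
  (n−1) standard deviation; the "±" of reported summaries is taken to be
  the sample sd.

## Synthetic phantom

The six-station assessment phantom places the marker at six poses evenly
spaced on a 100 mm circle around a symmetry point, stations i and i+3
antipodal. Ground-truth poses are generated by rotating one base pose
about the symmetry axis in 60° steps; every virtual target *on that
axis* is therefore mapped to one common world point by all six ideal
poses, making the ideal PPE exactly zero by construction — any measured
PPE is attributable to localization error. The *angle* phantom tilts the
base pose toward the symmetry point (default 30°). Virtual targets sit
at 25–175 mm along the axis; the 100 mm target is always present and is
the one reported for cross-phantom comparisons.

Rendering: each voxel receives background + contrast × occupancy, where
occupancy is the sphere partial-volume fraction computed by supersampling
(default 4³ points per voxel, fraction error ≤ 1/64), followed by
optional Gaussian blur, an optional low-order multiplicative bias field
(an MRI artifact knob), and additive Gaussian noise. Defaults: CT
background 40, features 3000, noise σ 15 (HU-like); MRI background 100,
features 1000, σ 20. Every stochastic operation takes an explicit seed;
nothing defaults to wall-clock. Distractor injection adds ellipsoidal
bright blobs at seeded random positions with a clearance (default twice
the blob diameter) from specified points. `reslice` emulates thick-slab
reconstructions by averaging slabs along z with thickness = spacing,
using nearest-slice slab boundaries for non-integer ratios.

### What the synthetic data does not show

The renderer is slab-ideal: it reproduces partial-volume averaging
exactly but has no scanner point-spread function, no reconstruction
kernel, no gantry/table effects, no metal or susceptibility artifacts,
and no anatomical background. Consequently absolute PPEs are smaller
than those measured on physical phantoms with real scanners, and some
thickness effects are muted: because all six station poses share the
same z-structure, common-mode z-quantization cancels out of the PPE on
the plane phantom. One effect that survives and is worth knowing about
is a partial-volume resonance when the feature diameter equals the slab
thickness (3 mm features at 3 mm slices): each feature then contributes
only one or two low-signal crescents per slab and the in-plane centroid
noise peaks, giving larger PPE at 3 mm than at 5 mm. The thin-vs-thick
ordering (1 mm better than 5 mm) is reproduced and asserted; a strictly
monotone PPE over 0.6→5 mm is not claimed, consistent with measured
repeatability orderings on physical setups also being non-monotone at
the thin end.

## Problem sizes used in the tests and acceptance script

Parameter recovery runs 4 configurations × 4 slice thicknesses × 24
random poses at zero noise (all geometries scanned CT-style: the
0.6|1|3|5 mm series is a CT protocol, and the MRI-only upper volume
bound is not meaningful at slab heights the modality is never acquired
at; MRI is exercised at its clinical voxel sizes 0.5×0.5×1.0 and
0.4×0.4×4.0 mm). Distractor robustness uses 500 seeded scenes with four
volume-plausible blobs. The acceptance script simulates full six-station
series for both phantoms, three CT configurations × four thicknesses
plus MRI at two voxel sizes, and six-scan repeat series — 186
localizations overall, a few minutes on one CPU.

## Known limitations

* Correspondence relies on distance uniqueness; markers whose distance
  gaps are below the measurement error at very thick slices fall back to
  the exhaustive-subset search, and beyond 16 plausible candidates the
  pipeline reports failure rather than guessing.
* Features must be completely captured in the volume (slice thickness =
  slice spacing); overlapping or truncated features merge or vanish and
  are then rejected by the distance check, not repaired.
* The scalar clipping-translation metric cannot see tangential remount
  shifts (use the vector variant for that).
* Non-rigid effects (skin shift, respiration) are out of scope; the
  marker-to-image transform is strictly rigid.
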