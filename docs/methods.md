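# Methods note

This note records the models, parameter choices and numerical decisions
behind `ablateguide`, a phantom-study toolkit for fiducial-registered,
optically tracked percutaneous liver ablation guidance, together with the
known limits of the synthetic generator.

## Coordinate conventions

All world coordinates are in millimetres. Volumes store intensities in
`(i, j, k)` index order with per-axis spacing, origin and an axis-aligned
direction; voxel index `(0, 0, 0)` is centred at the origin. NIfTI and
MetaImage I/O goes through SimpleITK, transposing between its `(z, y, x)`
array layout and ours; volumes with vector payloads (e.g. 4D NIfTI) are
rejected rather than silently flattened.

## Synthetic CT phantom

The generator is a deliberately simple geometric abdomen, not an anatomy
atlas. It exists to give every pipeline stage a scene with exact ground
truth: analytic organ shapes, known tumor centres and an exactly known
fiducial constellation.

- Grid: `(192, 192, 72)` voxels at `(0.75, 0.75, 2.0)` mm — roughly a
  clinical abdominal CT slab at reduced in-plane extent, sized so a full
  scene renders in a few seconds. The grid size is this package's own
  choice, made for test-runtime reasons; nothing downstream depends on it.
- HU palette: air −1000, soft tissue 45, tumor 30, spleen 100, liver 65,
  vessels 150, bone 700, fiducial markers 2000. Values sit near clinical
  means but the classes are piecewise-constant: there is no texture,
  beam hardening or partial-volume blur unless image noise is requested.
- Structures: ellipsoidal body and liver, spine as a cylinder, three
  intra-hepatic vessel capsules, spherical tumors (default one 15-mm
  lesion) placed with a bounded retry budget; placement failure raises
  rather than degrading silently.
- A 6-mm soft-tissue rind is kept between liver and skin so that surface
  markers and liver never touch — segmentation correctness tests rely on
  this separation being structural, not incidental.
- 20 skin fiducials are sampled on the anterior body surface with a
  minimum pairwise separation of 15 mm.

### Fiducial distinctness tolerance

Correspondence by pairwise-distance signatures needs the constellation's
190 pairwise distances to be mutually distinct. A distinctness gap of
2 mm across 190 distances would require a distance span above 378 mm —
geometrically impossible on a human-scale abdomen. The package therefore
uses a 0.1-mm distinctness tolerance for the 20-marker skin constellation
and keeps the stronger 2-mm gap only for the 5-marker needle clip, where
10 pairwise distances make it easily achievable. Robust matching does not
rest on the tolerance alone: signature voting is followed by a global
Hungarian assignment and an iterative refit, and validation is
Monte-Carlo (criterion: ≥ 99% exact recovery at σ = 0.5 mm with
occlusions) rather than a worst-case gap argument.

## Observation and breathing models

Tracked markers are modelled as a rigid world→tracker transform plus
i.i.d. per-axis Gaussian noise (default σ = 0.5 mm), independent
Bernoulli occlusion and a random permutation (identities unknown).
Breathing is a rigid sinusoidal translation of the internal anatomy,
`amplitude · sin(2πφ) · direction`, with skin motion attenuated by a
factor 0.3. This is a first-order stand-in: real hepatic breathing motion
is non-rigid and hysteretic. Sessions evaluate displacement analytically
instead of re-rendering the volume each frame.

## Registration

- Rigid fits use the closed-form SVD (Kabsch) solution with a
  reflection guard; degenerate (collinear, < 3 points) inputs raise.
- FRE is the RMS fiducial residual. With N markers and per-axis noise σ
  the expectation E[FRE²] = (1 − 2/N)·3σ² (0.675 mm² at N = 20,
  σ = 0.5 mm) is used as a statistical oracle.
- Correspondence: distance-signature voting → Hungarian assignment →
  iterative nearest-neighbour refit to a fixed point, with a
  triangle-hypothesis fallback and a brute-force permutation oracle for
  ≤ 7 markers. Matches with FRE above a configurable ceiling (5 mm,
  chosen to sit well above the expected sub-millimetre FRE regime but
  below any plausibly wrong correspondence) are rejected.

## Guidance

Trajectories are straight lines from a skin-surface entry voxel to the
target centre; among feasible entries the shortest wins, ties broken
lexicographically so planning is deterministic. Feasibility requires a
minimum clearance (3 mm) from forbidden structures, except within a
10-mm *target exclusion* zone around the target: structures abutting the
tumor itself (e.g. the feeding vessel) would otherwise make every entry
infeasible. This exclusion is a package design decision; its radius is
configurable.

Needle pose comes from the 5-marker clip: rigid fit of the clip model to
the observed markers (signature matching when identities are unknown),
then the calibrated tip offset and shaft axis are pushed through the
fitted transform. Alignment feedback is boundary-inclusive on both
thresholds (1° angular, 2 mm lateral). The simulated insertion loop
averages the clip pose over 5 frames (reducing noise by √5) and stops
when the estimated remaining depth is ≤ 0.05 mm; noiseless sessions end
within ~0.01 mm of the (voxel-rasterised) target centroid.

## Confirmation

- Pre/post alignment is **rigid**: centroid plus principal-axes
  initialisation (all four proper sign combinations tried), refined by a
  derivative-free Powell search maximising normalised correlation of
  Gaussian-smoothed masks, gated at Dice ≥ 0.5. Clinical confirmation
  software uses non-rigid registration; that is a declared divergence —
  rigid alignment is sufficient on phantoms and keeps an auditable
  oracle.
- Margin analysis uses the exact anisotropic Euclidean distance
  transform (`scipy.ndimage.distance_transform_edt` with physical
  sampling). The periablational shell is the 5-mm metric dilation of the
  tumor minus the tumor, optionally clipped to the liver. Residuals are
  `100·|X \ necrosis| / |X|`.
- Voxelisation bias: distances are measured between voxel centres, so a
  shell built at 1-mm voxels loses ~6% of its analytic volume at the
  outer boundary. Acceptance uses 0.5-mm voxels where the concentric
  sphere oracle lands within 1.5 percentage points of the analytic value.
- Technical success = complete tumor ablation (zero tumor residual) AND
  margin residual strictly below 10%. The boundary is strict: a residual
  of exactly 10.0% fails. Applied to the packaged per-target margin
  table this yields 12/15 margin successes (residuals 12.1%, 14.1% and
  10.1% fail); a published 13/15 figure is consistent only with a
  non-strict boundary at 10.1%, and the strict reading of "more than
  90% ablated" is retained and documented here rather than tuned.

## Reporting

Per-target session tables ship as CSV fixtures; decimal-comma cells
(European formatting, e.g. `"2,2"`) are normalised with a logged
warning. Summaries use the sample standard deviation (n − 1) with
rounding applied only at presentation (one decimal, `mean ± sd`).

## Known limitations

- Piecewise-constant HU phantom: segmentation thresholds are easy by
  construction; the segmentation stage validates plumbing and geometry,
  not clinical robustness.
- Rigid breathing and rigid pre/post registration (see above).
- Straight-line trajectories only; no needle bending, no gantry or
  probe collision model.
- Optical line-of-sight is reduced to an i.i.d. occlusion probability.
- The clinical 3.2-mm accuracy figure in the packaged tables is a
  patient measurement; the simulation arm makes property-based claims
  (monotonicity in noise, half-voxel noiseless bound), not a claim to
  reproduce that number.
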