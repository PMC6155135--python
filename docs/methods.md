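# Methods

## The neighborhood threshold

Segmentation is a per-voxel decision against the mean of a local
axis-aligned box. For a volume `V`, window shape `w` (one extent per
axis) and threshold percentage `t ∈ [0, 100]`, the box centered on voxel
`x` is clipped to the volume bounds; with clipped sum `S(x)` and clipped
voxel count `n(x)`:

- dark polarity: `x` is foreground iff `V(x) · n(x) ≤ S(x) · (100 − t) / 100`
- bright polarity: `x` is foreground iff `V(x) · n(x) ≥ S(x) · (100 + t) / 100`

`t` is the percentage by which a voxel must undercut (dark) or exceed
(bright) its neighborhood mean. `t = 0` marks voxels at-or-below (resp.
at-or-above) the local mean — the inequality is inclusive, so a perfectly
uniform region is fully foreground at `t = 0` and fully background at any
`t > 0`.

Box sums come from an N-D integral image (one cumulative sum per axis,
zero border) via inclusion–exclusion over the 2^N box corners, so the
cost per voxel is constant and the whole volume is one vectorized pass.
Integer and boolean inputs accumulate in `int64` and the decision is made
by cross-multiplication in integers — no division, hence bit-identical
results across runs and platforms. Float inputs are compared in double
precision. The rule is invariant to positive rescaling of the
intensities (both sides scale equally).

Numerical/geometric conventions:

- **Boundary policy**: windows are clipped, and the true clipped count is
  used — no padding. This avoids halo artifacts at stack edges. A
  consequence is that a window grown to the full volume is genuinely
  global only at the volume center; the explicitly global comparator
  (`preprocess.global_mean_threshold`) applies the same rule against the
  single volume-wide mean and is what the gradient benchmark compares
  against.
- **Even windows** are centered with the extra voxel on the lower-index
  side: the box covers `floor(w/2)` voxels before the center and
  `w − 1 − floor(w/2)` after.
- **Axis order** is `(z, y, x)`, 0-based, with `z` the slice index.
- **2D fallback**: `ndnt_threshold_2d_stack` thresholds each slice
  independently and is by construction identical to a 3D window with
  z-extent 1.
- **Tiling** (`tile_shape`) partitions the volume into blocks with an
  independent integral image per block and no blending at seams; trailing
  blocks may be smaller and there the window is clipped to the block.
  Overlapping tiles are supported but default off (later blocks
  overwrite). Hard seams are accepted behavior, not smoothed.

The threshold percentage is chosen by grid search
(`core.threshold_sweep`): candidates are scored by foreground fraction
and, when a reference mask exists, by mean Hausdorff distance, best
first. This keeps a human in the loop instead of an automatic criterion.

## Identification

The binary mask is cleaned (components below `min_size` voxels removed
first, then an ordered dilation/erosion schedule with box structuring
elements), labeled under a declared adjacency — face (6-neighborhood in
3D), face+edge, or full — and described per component:

- centroid = mean voxel index; bounding box is half-open;
- orientation = principal eigenvector of the voxel coordinate covariance,
  sign fixed so the first nonzero component (z, then y, then x) is
  nonnegative; elongation = largest/smallest eigenvalue (1 for a single
  voxel, infinite for an exactly flat scatter);
- mean intensity and the 16-bin histogram are always measured on the
  **raw** input volume (never the adjusted one) so reports are comparable
  across preprocessing configurations; histogram bins span the volume's
  global intensity range.

Face connectivity is the default because it is the conservative choice
against merge errors, the dominant failure mode when distinct structures
pass close to each other.

2D→3D stitching labels each slice in 2D and merges components in
adjacent slices whose same-(y,x) footprint overlap is at least
`min_overlap_voxels` (default 1), transitively via union–find. With face
connectivity and overlap 1 this reproduces direct 3D face labeling
exactly (a tested invariant). A relative-overlap mode (fraction of the
smaller footprint) is available but off by default.

Classification is first-match over user-defined rules ordered by unique
priorities; each rule is a conjunction of inclusive ranges over scalar
descriptors (voxel count, mean intensity, elongation, bbox extents).
Unmatched components are kept as "unassigned" or discarded, per config.
First-match was chosen over best-match because it is auditable and its
order is explicit.

Cross-channel gating segments a second channel with its own threshold
parameters, applies the same small-component cleanup (so isolated noise
voxels cannot gate anything in), and keeps primary components whose
intersection with the gate mask reaches `min_overlap` voxels.

## Reconstruction and the report

Each class is written to its own label volume with original ids; the
per-class voxel sets partition the foreground exactly. 2D flattening uses
the first-hit rule (each (y, x) column takes the id of its lowest-z
foreground voxel); alternatives change id assignment where objects stack
but not the binary footprint, which is the quantity tests rely on.

The statistical report gives, per class: object count, mean and
population standard deviation (ddof = 0) of voxel counts ("average size"
means mean voxel count, not equivalent diameter), and the mean minimum
intercentroid distance — centroid-to-centroid, reported only for classes
with at least two objects, in voxel units and additionally in physical
units when a voxel spacing is configured. The report embeds a SHA-256
fingerprint of the normalized configuration and can be filtered to a
bounding-box region (objects whose centroid falls inside); filtering to
the full volume reproduces the unfiltered report.

## Evaluation metrics

Distances are exact Euclidean distances between voxel centers, computed
with a Euclidean distance transform and anisotropy-scaled when a spacing
is given. The symmetric Hausdorff distance is the larger of the two
directed maxima; the mean variant is the mean over A-voxels of the
nearest-B distance averaged with the mean over B-voxels of the nearest-A
distance (flagged as this package's definition in the result metadata).
A per-slice mode averages the 2D value over z-slices, skipping slices
empty in both masks. Empty-mask conventions: both empty → 0; exactly one
empty → infinity (an output with no positive voxels). Voxel recall and
precision report `None` for 0/0. Object recall counts a truth object as
found when a *single* predicted component covers at least
`min_overlap_fraction` (default 0.5) of its voxels — split coverage does
not count.

## Synthetic study volumes

The generator plants spheres (cells; negative intensity offset = dark,
positive = bright labeled cells) and random-walk tubes (vessels and
axonal processes; overlapping unit-step balls with bounded curvature, so
each tube is one connected component by construction, and wall
reflections keep it inside the volume) onto a background with an optional
per-axis linear illumination gradient and additive Gaussian noise,
clipped to the output dtype. Objects are separated by at least
`min_separation` voxels via rejection sampling with a bounded attempt
budget (explicit error on unsatisfiable packings). Truth labels are the
exact planted voxel sets; everything is deterministic for a fixed seed.

Four presets define the study conditions used by the tests, the examples
and the acceptance script; all run in seconds at ≤ 32×64×64:

| preset | contents | background | noise σ | pipeline operating point |
|---|---|---|---|---|
| `xray_srb_like` | 10 dark cells (r 3–5, −60) + 1 dark vessel | 150, mild gradient | 6 | window (5,15,15), t=10, dark |
| `xray_alrb_like` | 8 dark cells, 5 bright cells (+60), 1 dark vessel | 140, mild gradient | 6 | window (7,21,21), t=15, both polarities |
| `ssem_like` | 6 dark cells + 2 dark processes (−70) | 160 | 7 | window (5,15,15), t=15, dark |
| `score_like` | 3 bright axons (+90), 2 of them in a gate channel | 40 | 6 | window (5,11,11), t=50, bright; gate min_size 30, min_overlap 10 |

Class rules per preset separate populations by mean intensity (dark vs
bright) and elongation (≥ 4 separates tubes from spheres). The ALRB-like
operating point uses a wider window and higher t than the
single-polarity runs: when both polarities are active, a tight window
lets background beside a large dark cell read as "bright" relative to
its dragged-down local mean (a halo) and bridge nearby objects; widening
the window dilutes that self-influence. The score-like gate is cleaned
with the same `min_size` as the primary channel because at t=50 and σ=6
a few per-mil of background gate voxels survive thresholding and a
single stray voxel would otherwise gate in an unlabeled axon.

The gradient benchmark (`gradient_benchmark_spec`) is the local-vs-global
demonstration: dark cells (−50) on background 100 with slope 2.5/voxel
along x (range ≈ 20–180 over 64 voxels). Cell centers are stratified into
equal-width bins along the gradient axis so every realization has cells
at both the dim and the bright end; cells on the bright end sit above the
volume-wide threshold and are necessarily missed by the global rule,
while the neighborhood rule recovers all of them. Stratification makes
the comparison a deterministic property of the benchmark rather than a
sampling accident.

What the phantoms do *not* emulate: realistic electron-microscopy
texture, point-spread functions, Poisson/shot noise, partial-volume
effects, touching or overlapping structures, and annotation error in the
ground truth. Passing the synthetic benchmarks therefore demonstrates
correctness of the algorithms and robustness to smooth illumination
drift and moderate additive noise — not performance on any particular
real dataset, where window, t and filter rules must be chosen per volume
(the sweep exists for exactly that).

## Problem sizes and determinism

The test bench and `scripts/acceptance.py` use volumes up to 64³ for the
overflow probe, 32³ for oracle-equivalence checks (brute-force
neighborhood sums by explicit slicing), 16³ for pairwise Hausdorff
oracles, and the preset shapes above for end-to-end runs — sizes at
which every brute-force oracle is exact and fast. All randomness flows
from explicit seeds (`numpy.random.default_rng`); the acceptance script
derives every stream from its `--seed` argument.

## Known limitations

- No GPU path and no overlap-blended tiling; tiled runs show hard seams.
- Windows are specified in voxels, not physical units; anisotropic data
  should get anisotropic window extents by hand.
- Merged objects are not split (no watershed/seeded separation); the
  conservative face connectivity is the only mitigation.
- Vessel statistics are voxel volume and bounding-box extent; no
  skeletonization or per-branch length.
- The mean-Hausdorff definition is the symmetrized average directed
  distance; other conventions exist, and the per-slice mode is provided
  for comparability with slice-based reporting.
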