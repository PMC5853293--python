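# Methods

This note documents the models, algorithms and numerical choices behind
`ctcount`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## The counting problem and the estimator

The tissue of interest (a pollinium or an ovary) is stained so that the
objects to be counted are the brightest structures in a reconstructed
micro-CT volume. Counting reduces to a stereological estimator: segment
the stained material, count objects `n` in a subset where they are
individually resolvable, measure the segmented volume `V_subset` of that
subset and `V_total` of the whole structure, and report

    v̄ = V_subset / n        N = V_total / v̄ = V_total · n / V_subset.

Both volumes are measured on the *same* scan (for pollen, the overview
scan; for ovules, the only scan). This matters: thresholding a blurred
sphere at the half-maximum grey level underestimates its volume by a
curvature term (roughly `σ²/r` of the radius), but since the identical
shrinkage applies to numerator and denominator it cancels in `N`.
`N` is reported both as a raw float and rounded half-up; when the subset
is the whole volume the estimator reduces exactly to the direct count.

Scale equivariance holds by construction: multiplying all voxel spacings
by `c` scales every µm³ quantity by `c³` and leaves `N` unchanged.

### Edge handling of the subset

Three rules are provided for attributing objects to a subset window:
`centroid` (count objects whose centre of mass lies in the half-open
box), `counting_frame` (count objects intersecting the box except those
touching its low-z/low-y/low-x faces — the classical unbiased brick),
and `all`.

For the two-scan pollen workflow the subset is a *pre-cropped* scan, and
there the plain centroid rule is biased upward: every grain cut by the
scan border leaves a fragment whose centroid lies inside the scan, so
boundary grains are counted roughly twice as often as they should be.
The counting-frame rule on a cropped scan errs in the opposite direction
because fragments below the validation floor silently vanish from the
inclusion faces. The default for cropped subset scans is therefore a
**guard zone** (`guard_um`): centroids are counted only in a window at
least one maximum object radius inside the scan border, and the subset
volume is measured on the matching shrunk window of the overview scan
(snapped to whole overview voxels so both measurements cover the same
physical box). Inside the guarded window every counted centroid is a
true object centre, making the centroid rule exactly unbiased under
stationary object placement. `guard_um` should be at least
`r_max + 2·σ_blur`; the validation phantoms use 9 µm for grains of mean
radius 5 µm.

## Calibration

Byte scaling maps a chosen grey window `[gmin, gmax]` linearly to 0–255
with clamping and half-up rounding. CT scaling fits the unique linear
map sending the measured mean grey of air and of a reference liquid
(1 % PTA in FAA; measured density 0.937 g ml⁻¹, carried as metadata
only) to configurable targets, default 0 and 1000 — the published
procedure defers the target scale to the instrument manual, and a
two-point linear map is the only consistent reading. Calibrated volumes
stay floating point; quantisation happens only at file export. The
useful invariant is gain invariance: any affine distortion of a raw scan
plus its matching dummy calibrates to identical output (verified to
< 1e-9 voxelwise).

## Filtering chain

Fixed order: greyscale threshold → 3×3×3 median → 9×9×9 Gaussian →
object separation. Greyscale is retained inside the mask (sub-threshold
voxels are zeroed, not binarised) because the separation step operates
on intensities. Both filters use mirror (reflect) padding so objects at
scan edges are not darkened, which would bias volume estimates. The
Gaussian support is 9³ voxels; its σ is configurable with default 1.5
voxels (≈ 6σ support). The threshold is operator-chosen per specimen
(config value) with an optional Otsu mode; for the rendered phantoms the
natural choice is the half-maximum grey, the midpoint of background and
foreground levels.

## Iterative-threshold separation of touching objects

Touching grains merge under any single threshold. The splitter sweeps
thresholds from the volume's maximum grey down to the preprocessing
threshold in decrements of `step` (default: 1 grey level for integer
volumes, (max−min)/255 for float volumes) and maintains the component
merge-tree across levels: bright cores appear as separate components at
high thresholds and fuse as the threshold drops. Each region track
("branch") records its voxel count at every level; a branch *validates*
at levels where its physical volume lies in `[vmin, vmax]` µm³, and its
representative threshold is the validated level with the smallest
relative volume change against the previous level (MSER-style
stability; at a merge node the reference is the children's combined
volume; ties resolve to the higher threshold, which favours splitting).
Selection is bottom-up: if any descendants of a branch were selected,
they win over the (merged) parent. Selected components are rasterised at
their selected thresholds; the tree structure guarantees they are
disjoint. Output labelling is deterministic (ordered by the raster
position of each branch's seed voxel), so identical inputs give
voxel-identical label maps. A `max_count` criterion (single global
threshold maximising the number of in-range components) is provided as a
simpler alternative.

The volume bounds are specimen-specific, mandatory configuration — the
original per-species values are not published. For phantoms with
expected grain volume `v̄ₑ`, the analyses here use
`[0.03·v̄ₑ, 6·v̄ₑ]`: the lower bound must admit the small bright cores at
which touching grains first separate (cores near 3–10 % of the full
grain volume), while staying above the scale of noise clumps; the upper
bound only needs to reject the fused whole-pollinium component.
6-connectivity is used for the splitting analyses (it breaks the thin
one-voxel bridges that 26-connectivity preserves between tangent
grains); 26 remains the default for plain component counting of
resolvable objects.

### Accuracy and its physical limit

On full-scale phantoms (3 000 grains of mean radius 5 voxels, 15 % CV,
PSF σ = 1 voxel, SNR 10, 256³) the end-to-end pollen workflow recovers
the true count within ~4 % for dense touching packings and within ~2 %
for loose packings; an 800-ovule ovary phantom recovers within ~2 %.
The residual undercount in dense packings is a resolvability limit, not
an algorithmic artefact: grain pairs whose centre distance falls to
0.95·(r₁+r₂) (the generator permits 5 % overlap) develop a contact neck
whose blurred intensity dip is shallower than the noise floor, so no
threshold separates them and the pair validates as one object. The
subset size drives the estimator's variance: with `n` grains in the
subset the coefficient of variation of `v̄` is ≈ 0.45/√n for 15 %
radius CV, so subsets of ~1 000 grains keep sampling error near 1 %.

## Synthetic phantoms

The generators are pure functions of a spec and a seed, with exact
ground truth (centres, radii, cluster membership) independent of
rendering parameters.

* **Packing.** Random sequential addition, largest sphere first, inside
  a spherical container (pollinium) or the full box (loose mode), using
  a uniform-grid neighbour search. Every sphere keeps a *fixed*
  maximum-radius margin from the container wall: a radius-dependent
  margin would enrich the wall layer in small objects and break the
  stationarity that subset extrapolation relies on. Touching mode
  allows tangency down to `1 − max_overlap_frac` (default 0.05) of the
  centre distance; loose mode enforces a 1.25× clear separation. The
  default packing fraction is 0.30 (0.28 is used for the 3 000-grain
  phantom; random sequential addition saturates near 0.38).
* **Massulae mode** samples cluster weights from a lognormal (σ = 0.8 —
  a few large and many small sub-aggregates), places cluster centres by
  rejection sampling with mild allowed interpenetration, then packs
  grains within each cluster.
* **Ovary mode** strings ovules along a cylindrical placenta, uniform in
  axial position, with an optional contiguous gap covering a chosen
  fraction of the axis (emulating the patchy ovule distributions of
  top-of-inflorescence gynoecia). Ovules keep the 1.25× separation
  because the single-scan workflow presumes they are resolvable.
* **Rendering**: solid spheres at a foreground grey (default 200 over
  background 20), Gaussian PSF blur, optional linear axial shading,
  additive Gaussian noise (default sd 18, i.e. SNR = 10 — CT
  reconstruction noise is approximately Gaussian after filtered
  back-projection).

What the phantoms do **not** emulate: grain asphericity and
deformation at contacts, exine texture, beam hardening, ring artefacts,
scatter, and partial staining gradients within objects. Passing the
phantom suite therefore demonstrates the estimator and separation logic
under realistic blur/noise/aggregation, not robustness to every scanner
artefact; on real material the operator still chooses the threshold and
volume bounds per specimen.

* **Flower-count tables** draw per-flower pollen and ovule counts from
  per-species truncated normal distributions whose means and spreads
  follow the eight-species study design (five deceptive, three rewarding
  Orchidinae; 2–4 inflorescences × three flower positions), with
  multiplicative position effects (default: ovules decline 1.3→1.0→0.7
  from bottom to top, pollen flat, matching the study's findings). The
  generating parameters are the ground truth for power/type-I checks.

## Statistics

* **PERMANOVA** follows the Gower-centred partitioning: with
  `G = −½·J D² J`, `SS(model) = tr(H G)` for the design's hat matrix.
  Terms are added sequentially (Type-I) in the order given, interactions
  as products of treatment-coded dummies, matching `adonis` semantics
  (verified against vegan's `adonis2` during development: identical SS,
  F and R²). Pseudo-F per term is `(SS_t/df_t)/(SS_res/df_res)`;
  p-values use free permutation of raw observations,
  `p = (#{F* ≥ F} + 1)/(n_perm + 1)`, with permutations applied to G's
  rows and columns and vectorised in chunks. On univariate data with
  Euclidean distance the pseudo-F equals the classical ANOVA F exactly.
  Residual SS below `1e-12·SS_total` is treated as an exact zero so
  perfectly separated groups yield F = ∞ rather than noise-sign
  artefacts. Bonferroni post hoc: pairwise one-way tests with
  `p_adj = min(1, p·n_pairs)` and a deterministic compact-letter
  display.
* **Exact MWW**: W is `min(U₁, U₂)` (smaller-is-extreme convention,
  0 ≤ W ≤ n₁n₂); the exact two-sided p doubles the smaller tail of the
  complete null distribution of U, computed by the classical counting
  recurrence `N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1)` while
  `C(n1+n2, n1) ≤ 10⁶` and there are no ties; otherwise a normal
  approximation with tie and continuity correction is used and flagged.
  Identical samples fall on the tie path and give p = 1 (z = 0).
* **Summary tables**: per-species mean, SE (= sample sd/√N, ddof 1),
  variance and N for pollen, ovules and per-flower P:O (P:O is always
  computed per flower, never as a ratio of group means); per-strategy
  N-weighted means of species means (algebraically the pooled per-flower
  mean) with pooled SE; and the ratio of mean per-species P:O variances
  (rewarding/deceptive).

## Phylogenetic comparative layer

The Brownian-motion tip covariance is `C_ij =` shared root-to-MRCA path
length. Pagel's λ multiplies off-diagonal entries only, searched on
[0, 1] (the interpretable range) by bounded scalar ML with the BM rate
σ² and root mean profiled analytically at each λ; a 1001-point grid and
both endpoints guard the optimiser against local optima. Likelihoods are
full ML, not REML. The binary-trait model is the symmetric 2-state
Markov chain (q01 = q10 = q) with likelihood by Felsenstein pruning and
a stationary (½, ½) root prior; the rate is optimised on a log scale
relative to the mean tip depth. An optional joint λ transform for the
discrete trait scales internal branches by λ while preserving tip
depths; both the plain SYM fit and the joint fit are available because
published analyses are ambiguous about which was used. PGLS estimates
`β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V` the λ-transformed BM covariance, λ
fitted by ML on the residual likelihood (or fixed); with λ = 0 the fit
reduces exactly to OLS, coefficient SEs use the unbiased σ² (n−p
denominator) and t-tests with n−p df.

The study's own 7-species tree is not published with branch lengths, so
trees are user input and validation is simulation-based parameter
recovery: mean λ̂ ≥ 0.9 over 200 BM simulations on random 50-tip
coalescent trees, median λ̂ ≤ 0.1 for i.i.d. traits, and ≥ 90 % coverage
of a known PGLS slope at ±2 SE.

## Problem sizes used in the validation suite

The full-scale phantom tests use 3 000 grains in 256³ voxels (touching
and loose) with a 140³/200³ high-resolution subset, an 800-ovule 256³
ovary, 20 small phantoms for self-consistency, 1 000 null datasets × 999
permutations for type-I calibration, and 400 λ fits plus 100 PGLS fits
for the phylogenetic recovery checks. The whole suite runs in roughly
ten minutes on one CPU; the threshold sweep for the big phantoms uses
`step = (max grey − threshold)/100`, which resolves grain-scale
stability plateaus while keeping the sweep to ~100 labelling passes.

## Degenerate inputs and tie-breaks

Empty foreground, inverted volume bounds, coincident calibration greys,
zero ovule counts, constant traits, single-state discrete traits,
saturated designs and rank-deficient PGLS designs all raise immediately
with specific messages. Stability ties select the higher threshold;
PERMANOVA permutation counts use a `(1 − 1e-12)` relative tolerance on
the F comparison; label order is raster-deterministic everywhere.

## Known limitations

* Dense aggregates beyond ~0.95 centre-distance contact are fused at
  acquisition physics level; the splitter cannot (and should not)
  separate them, so counts in extreme packings are biased low by a few
  per cent.
* No image registration: the subset ROI must be supplied in overview
  coordinates by the operator.
* The iterative split assumes objects are brighter at their cores than
  at contacts; hollow or shell-stained objects would need inverted
  logic.
* The CT-scaling target scale (0/1000) is a convention, not a Hounsfield
  calibration; no beam-hardening or drift correction is attempted.
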