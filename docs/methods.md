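# Methods

This note records the models, parameter choices and numerical decisions
behind `pedseg`, and what the phantom-based validation does and does not
establish.

## Coordinate and raster conventions

A volume is an `(nx, nB, nz)` array: `x` lateral within a B-scan, `B` the
B-scan index, `z` axial depth increasing downward. Surfaces are integer
height maps `z(x, B)`; the height is the z index of the boundary voxel
itself, with each surface voxel belonging to the tissue band above it
being bright-side: the ILM and EZ roof are the *first* bright voxel of
their band, the RPE floor the *last*. The slab "between surfaces A and B"
is the half-open range `(z_A, z_B]`, so consecutive slabs partition the
retina without overlap; the PED mask is the `(z_RPE, z_BM]` slab.
Intensities are greyscale on `[0, 255]`. Clinical-scale spacing
(11.72 × 93.75 × 3.50 μm) is carried through I/O but the algorithms work
in voxel units: within one acquisition protocol the spacing is constant
and cancels out of the classifier and the overlap metrics.

## Phantom generator

The generator paints noise-free intensity bands between four smooth
surfaces and then applies multiplicative unit-mean gamma speckle
(`k = 1/scale²`), clipped to the raster range. Defaults (a desk-scale
128 × 16 × 160 grid) were chosen so whole-pipeline experiments run in
seconds per volume while preserving the geometry that stresses the
method:

* band levels background 10, NFL 130, ONL 45, EZ 140, RPE 170, PED lumen
  30 — the ILM is the most prominent dark-to-bright edge (jump 120 vs. 95
  at the EZ roof), as the staged surface search assumes;
* the PED is a half-ellipsoid lift of the RPE floor above a planar,
  slightly tilted BM baseline (an affine baseline is exactly recovered by
  the convex hull, so BM-estimation error is attributable to the RPE
  search, not to the phantom);
* the confounding fluid pocket is a dark half-ellipsoid notch carved into
  the EZ/RPE band with its floor on the RPE floor — subretinal fluid. It
  reliably pulls the bright-to-dark RPE search up to the notch roof,
  which the convex hull then bridges, creating exactly the class of false
  positive the AdaBoost stage exists to remove;
* the randomized study condition draws one PED (half-width 14–22 voxels,
  apex 10–18) and one confounder (half-width 7–11, apex 6–9, placed
  laterally clear of the PED), with speckle scale 0.25.

What phantoms do **not** emulate: A-scan point-spread and sensitivity
roll-off, shadowing under hyper-reflective material, vessel artifacts,
motion between B-scans, curved BM with non-convex baseline, or multiple
interacting pathologies. Passing the phantom study shows the pipeline's
stages are implemented correctly and cooperate; it does not certify
clinical-grade accuracy on real eyes.

## Denoising

MCDE (conductance-modulated mean-curvature flow) with exponential
conductance `c(g) = exp(−(g/K)²)`, explicit scheme on half-point face
gradients, Neumann boundaries. Defaults `K = 2.0` on intensities rescaled
to `[0, 1]`, 5 iterations, time step 0.125 (stability bound 0.25 for the
2D stencil). Diffusion is 2D per B-scan: at ~94 μm slice spacing,
cross-slice diffusion would mix unrelated tissue. A constant image is an
exact fixed point of the discrete update (flux is built from raw
differences, so zero difference gives exactly zero flux).

## Optimal-surface search

The single-surface problem — minimize the summed voxel cost of a height
map subject to `|Δz| ≤ δ` between 4-adjacent columns — is solved exactly.
Cost is the negated polarity-matched axial difference (backward difference
for dark-to-bright, forward for bright-to-dark, putting the optimum on the
bright boundary voxel). Two solver paths share one contract:

* `nB = 1`: dynamic programming with a sliding-window minimum, exact in
  float arithmetic;
* `nB > 1`: the minimum-closed-set reduction solved as a min s-t cut.
  Capacities are scaled to integers (sum budget 2³⁰, hard constraints at
  int32 max) for `scipy.sparse.csgraph.maximum_flow`; a BFS over the
  exact integer residual graph returns the *minimal* source side, which
  makes the tie-break deterministic: among equal-cost optima the
  pointwise-smallest (hence lexicographically smallest) surface.

Bands are tightened to mutual consistency by interval propagation before
graph construction; emptiness raises an infeasibility error. Multi-scale:
two factor-2 mean-pooling downsamplings along z, each coarse solution
constraining the next scale to ±8 voxels (margin exposed; it must exceed
the ≤2-voxel upsampling error, and 8 leaves slack for pooling blur).
Coarse-scale lower band bounds are divided with ceiling so a voxel
excluded at full resolution cannot re-enter at coarse resolution.

Stage order and defaults: ILM (dark-to-bright, δ = 1, full band), EZ roof
(dark-to-bright, δ = 4, below ILM + 2), RPE floor (bright-to-dark, δ = 4,
below EZ roof + 2). The larger δ for the outer surfaces admits the abrupt
arch of a serous PED; δ and the gaps are configuration.

## BM estimation and the initial mask

Per B-scan, BM is the max-z chain of the convex hull of
`{(x, z_RPE(x))}` — as a function of x this is the concave majorant of
the trace (on screen, with z downward, the convex lower boundary). The
float envelope is floored (with a 1e−9 guard against ties at integers)
rather than rounded: flooring halves the systematic upward bias the
envelope inherits from riding the upper tail of per-column noise, and it
suppresses one-voxel slivers that would otherwise bridge separate arches
into one candidate region. The hull is 2D per B-scan, not 3D: B-scans sit
~94 μm apart and the clinical display convention draws per-B-scan BM
lines.

## Features and classification

Features are extracted per 8-connected 2D component, B-scan by B-scan
(abrupt slice-to-slice variation of PED cross-sections makes 2D the
robust choice; 3D context is a known limitation). Interpretations fixed
here: "bright pixels" = above the B-scan's Otsu threshold; directional
extrema = the region pixel with maximal projection on each of 8 compass
directions (raster-order tie-break); the bounding rectangle is
axis-aligned; ellipse features follow the normalized-second-central-
moment (regionprops) convention; Hessian eigenvalues (Gaussian scales 1,
3, 6, 9, 14) are ordered by magnitude, the blob-analysis convention.
Surface distances are signed (centroid z minus surface z), informative
about which side of a layer a region sits on.

AdaBoost is implemented directly — decision stumps over single features
with exhaustive midpoint thresholds, `α = ½ ln((1−ε)/ε)`, multiplicative
reweighting and renormalization — because the reweighting identity
(misclassified mass = ½ after each round) and the exponential training-
error bound are part of the tested contract. 50 rounds by default with
early stopping at ε = 0 (α capped via ε ≥ 1e−12) or ε ≥ 0.5; ties in
stump selection break toward the lowest feature index, then threshold.
Training labels: a candidate region is positive when ≥ 50% of its pixels
overlap the truth mask. Regions are kept or deleted whole.

## Graph cut

Energy per the three-term model with weights on the simplex. Adopted
forms: Boykov–Jolly region term from 64-bin seed-intensity histograms
with add-one smoothing; boundary term `exp(−ΔI²/2σ²)` with σ the standard
deviation of all 6-neighbor differences; shape term
`S_p(obj) = min(d(p)/r, 1)` with `d` the Euclidean distance transform of
the refined mask (voxel metric; anisotropy deliberately ignored for
consistency with the voxel-unit features) and `r` the region's
near-minimal enclosing-sphere radius (Ritter's deterministic
approximation, floor 0.5 voxels). Each voxel inherits `(d, r)` from its
nearest region via the distance transform's nearest-site indices.

The cut runs in 3D with 6-connectivity (smallest submodular
neighborhood). Seed voxels are contracted into the terminals — exactly
equivalent to infinite t-links but the flow problem spans only free
voxels — and the solve is restricted to the bounding box of all seeds;
outside the background-seed boxes everything is background by
construction. The brightness transform (per-column monotone remap pinning
the EZ–RPE slab median to 200 and the background median to 30) normalizes
contrast before histograms are built.

Default weights `(λ_R, λ_S, λ_B) = (0.4, 0.2, 0.4)`; the training
protocol refines `(λ_R, λ_S)` by projected finite-difference gradient
ascent on mean Dice over the training volumes (λ_B = 1 − λ_R − λ_S,
backtracking steps, monotone acceptance — the result never scores below
the initialization). On the phantom study the ascent settles around
`(0.1, 0.1, 0.8)`: with strong PED/background contrast the boundary term
carries most of the localization.

## Morphology

Adaptive ball radius `r = c · V^{1/3}` (round half up) — dimensionally a
length from a volume, with c < 1 shrinking and c > 1 growing relative to
the region scale. Ball erosions/dilations are computed through the exact
Euclidean distance transform (identical to structuring-element morphology,
but independent of the SE size). Post-processing per 26-connected
component: opening-by-reconstruction (marker = erosion at c = 0.200,
6-connected geodesic reconstruction — removes components that erode away
and diagonally-attached spurs, restores the body exactly) then closing at
c = 0.700 (padded so growth is never clipped). A 1-voxel region has
radius 0 and passes through unchanged; the adaptive radius is what
protects small genuine regions. Idempotence holds on the blob-like masks
the pipeline produces and is tested there.

## Evaluation

TPVF `= |A∩G|/|G|`, FPVF `= |A\G|/(|R|−|G|)` (false-positive-eligible
denominator, the Udupa convention), DSC, PPV; empty-truth and empty-auto
cases carry explicit flags instead of NaNs. Paired t-test is two-sided
with df = n−1, refusing zero-variance non-zero differences. Bland–Altman
limits use the sample standard deviation (n−1) and ±1.96. Volumes for
agreement plots are exported in mm³ (voxel count × voxel volume).

## Problem sizes used in validation

The automated study trains on 20 phantoms and tests on 10 (one PED + one
confounder each, speckle 0.25); oracle-equivalence checks run exhaustive
enumeration on instances small enough to enumerate (surfaces up to
5 × 6 columns × depths; graph cuts up to 12 voxels; hulls up to 40
columns). These sizes give exact, reproducible cross-checks of the same
code paths the full-scale pipeline uses.

## Known limitations

* 2D feature extraction and per-B-scan BM estimation ignore cross-slice
  context.
* BM estimation assumes a convex (in the hull sense) baseline; eyes with
  BM undulation concave to the vitreous will be bridged incorrectly.
* Fluid above the RPE floor is only *rejected* (by classification), not
  segmented; adjacent subretinal fluid inside a PED's background-seed gap
  can still be annexed by the cut when the energy weights under-weight
  the shape term.
* Proprietary vendor formats are not parsed; convert to TIFF/NIfTI.
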