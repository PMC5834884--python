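# Methods

`synquant` quantifies chemical synapses in 3D reconstructions of cortical
neuropil of the kind produced by FIB/SEM volume electron microscopy after
semi-automated segmentation. The package covers the full analysis chain —
stereology, unbiased counting, synaptic apposition surface (SAS)
morphometry, spatial point-pattern statistics and two-group comparison —
and ships a synthetic-data generator that emulates the statistical
structure of segmented study material so that every stage is testable
without imaging data. This note records the models, the defaults and the
genuinely open design choices.

## Coordinate and unit conventions

All 3D coordinates are physical nanometres with the origin at the stack
corner, x/y in the imaging plane and z along the milling axis. Intervals
are half-open `[min, max)`. Synapse densities are per μm³, SAS areas in
nm², cortical thickness in mm. A reference stack is 2048 × 1536 pixels at
5 nm/pixel with 20 nm sections.

## Stereology

**Cavalieri point counting.** Volume fractions of neurons, glia, blood
vessels and neuropil are estimated on semithin-section label images by a
systematic point grid (default 400 μm² of tissue per point) with one
uniform random origin offset (a systematic-random sample; the offset seed
is recorded). The neuropil fraction is the complement
`V_n = 100 − (V_neu + V_g + V_bv)`, so the four fractions sum to exactly
100 by construction. The point-count estimate converges to the exact
pixel fraction as the grid densifies; the tests verify this against an
exact pixel tally.

**Shrinkage.** EM processing shrinks tissue; the area shrinkage factor is
`p² = area_after / area_before` (measured value for this kind of material:
0.933). Measurements made on processed tissue are scaled *up*:
a d-dimensional measure is divided by `p²^(d/2)`; per-volume densities
are equivalently multiplied by `p²^(3/2)`. The direction of the
correction is a design decision — it is validated by reproducing the
printed corrected stack-volume range (260.2–824.4 μm³) from the raw stack
geometry within 0.1%, which fails in the opposite direction. Values of
p² > 1 (swelling) are accepted but flagged. Whether cortical thickness
should also be corrected is unclear from the source material; thickness
is reported uncorrected here.

**Artifacts.** Fixation artifacts (swollen processes) contain no
countable synapses; their volume is subtracted from each counting volume
before densities are formed. In real material it spans 3–33% of a stack.

## Unbiased counting

The counting frame is the 3D unbiased brick: three inclusion faces
(maximum-coordinate), three exclusion faces (minimum-coordinate) with
extension planes. An object is counted iff it intersects the brick and
touches no exclusion surface. Extents here are axis-aligned bounding
boxes of whole reconstructed junctions, which are convex, and for convex
axis-aligned extents the rule reduces to: *counted iff the minimum corner
lies in the half-open frame*. (If the min corner is below the frame on
an axis while the box reaches the frame, the box crosses that exclusion
plane; a box whose min corner is past an inclusion face cannot intersect
the brick at all.) The tests verify this reduction against a brute-force
voxelised implementation of the full rule, and verify unbiasedness: over
random stationary patterns the mean density estimate equals the true
intensity for different frame sizes.

Objects truncated by the physical stack boundary are flagged
"incomplete" and discarded before frame logic — the two-step discard used
when segmenting real stacks. This makes the guard zone (window margin
outside the frame) a bias parameter: it must be at least as large as the
largest plausible object extent, otherwise frame-qualified objects get
discarded as incomplete and densities are biased low. With log-normal SAS
areas (σ = 0.8, mean 117,800 nm²) the 99.9th-percentile extent is below
1 μm, so the default margin is 20% of a 5 μm window (1 μm guard); the
residual bias is ≪ 1%.

The hierarchy of the estimates is preserved throughout: stack → case mean
→ group mean ± SD. Group statistics are always computed over cases (the
independent sampling unit), never over stacks.

## SAS morphometry

The SAS is an open triangulated surface. Area is the triangle-area sum;
perimeter is the length of the single open boundary loop (meshes that are
closed or have several boundary loops are rejected). The curvature
statistic is

    curvature = 1 − projected_area / area,

zero for a flat SAS and approaching 1 as the surface closes on itself
(hemisphere: 0.5). Two choices are open in this definition and fixed
here:

* **Projection plane** — the least-squares best-fit plane of the
  vertices (principal axes of the vertex cloud). This is
  rotation-invariant; a fixed laboratory axis would not be.
* **Projected area** — the area of the *union* of the projected
  triangles, not their sum. A folded surface projected as a sum would be
  double-counted, which could push the curvature below zero; the union
  counts overlaps once and guarantees `0 ≤ curvature < 1`. The union
  (computed with GEOS polygon operations) is verified against an
  independent rasterisation oracle within 0.5%.

SAS size distributions are summarised per group × synapse type as
mean ± SEM (SEM undefined and flagged for singleton cells; empty cells
reported absent, not zero), binned with the Freedman–Diaconis rule by
default, and fitted by a log-normal via the closed-form ML fit on
log-values with a one-sample KS statistic of log-values against the
fitted normal as the goodness-of-fit check (the p-value is the standard
approximation, not Lilliefors-corrected; it is used descriptively).

## Spatial statistics

Synapse centroids are compared with complete spatial randomness (CSR,
the homogeneous Poisson process) through the nearest-neighbour distance
CDF **G**, the empty-space function **F** (regular grid of test
locations) and Ripley's **K** in 3D:

* G and F use the reduced-sample (border) correction — a point or test
  location contributes at distance r only if it lies at least r from the
  window boundary. The reduced-sample estimator is not guaranteed
  monotone in r (monotonicity is tested on the uncorrected estimator;
  the corrected ones are verified to stay in [0, 1]).
* K uses the translation correction,
  `K̂(r) = |W|²/(n(n−1)) Σ_{i≠j} 1(d_ij ≤ r)/w_ij` with
  `w_ij = Π_a (L_a − |Δ_a|)`.
* CSR references: `G(r) = F(r) = 1 − exp(−λ·4/3·π r³)`,
  `K(r) = 4/3·π r³`.
* The default r-grid is 512 points from 0 to a quarter of the shortest
  window side; grids reaching past half the shortest side are truncated
  with a warning.

Envelope tests simulate (default) 100 CSR patterns *conditioned on the
observed n* (binomial processes — the standard envelope convention) and
take the pointwise min/max (rank-1 envelope). The reported
`outside_fraction` is the fraction of r-grid points where the observed
curve exits the envelope; under CSR its expectation is 2/(n_sim+1) ≈ 2%
per point, and the "departs from CSR" flag fires above 5%. Because
summary functions are strongly autocorrelated in r, a CSR pattern
occasionally (≈ 2% of seeds) exits over a large contiguous range — the
rank-1 envelope controls the pointwise rate, not a global one; global
envelopes are out of scope.

The raw mean nearest-neighbour distance in a bounded window is biased
upward by edge effects (≈ +3% in a 10 μm cube at 0.5 μm⁻³); `nn_mean`
offers minus-sampling (a guard zone, neighbours searched among all
points) which removes the bias — with a 2 μm guard the recovered mean
matches the Poisson closed form `Γ(4/3)·(4πλ/3)^(−1/3)` to a few tenths
of a percent.

**Dead space.** Synapses are extended objects that cannot overlap, so G
is identically zero below the hard-core diameter; `dead_space_radius`
reports the largest r with Ĝ(r) = 0 (equal to the minimum NN distance up
to grid resolution).

## Group statistics

Two-group comparisons use the unpaired two-sided Mann-Whitney U test on
per-case values (cases, not stacks, are independent), exact by
enumeration when the pooled sample is tie-free with ≤ 12 observations and
otherwise via the normal approximation with tie and continuity
corrections. Pooled per-synapse SAS size distributions are compared with
the two-sample KS test (pooling, rather than per-case distribution
comparison, is a design choice). No multiple-testing correction is
applied. At n = 5 vs 5 the exact U test is discrete: the largest
attainable level not exceeding 0.05 is 8/252 ≈ 0.032, so the test is
conservative; the calibration tests assert the realised null rejection
rate against that attainable size and against the binomial upper bound of
the nominal 0.05, both fixed before running.

## Synthetic-data generator

The generator is first-class code: its defaults *are* the study
conditions the analysis is validated under.

* **Positions**: random sequential adsorption (RSA) at a fixed target
  count `round(λ·V_valid)` with hard-core radius 250 nm (configurable;
  the true biological hard-core scale is not identifiable from summary
  data — the default is half the smallest plausible inter-synapse
  spacing consistent with the observed dead space, not a biological
  claim). Saturation raises an explicit error naming the achieved count.
  With radius 0 the generator degenerates to a binomial (fixed-n CSR)
  process.
* **Intensities**: control 0.51 μm⁻³, disease 0.37 μm⁻³.
* **Types**: Bernoulli AS labels, control 95.64%, disease 94.47%.
* **SAS**: randomly oriented spherical caps — the only simple surface
  family whose area and projection curvature are independently
  controllable (cap with half-angle θ: curvature `(1 − cos θ)/2`, area
  `2πR²(1 − cos θ)`). AS areas are log-normal with σ = 0.8 and
  `μ = ln(mean) − σ²/2` so the arithmetic mean matches the group value
  (control 117,800 nm², disease 123,200 nm²); SS areas are scaled by the
  group SS/AS mean ratio. Per-synapse curvature is Normal(0.049, 0.01)
  clipped to (0, 0.95). The triangulated cap is uniformly rescaled so
  its discrete area equals the request exactly (scaling preserves the
  projection ratio); discrete curvature converges to the analytic value
  as resolution grows (≈ 0.1% at the default 200 triangles for shallow
  caps).
* **Artifacts**: axis-aligned ellipsoids, one per cell of a jittered k³
  grid so non-overlap is guaranteed and the analytic total volume equals
  the requested fraction exactly (feasible up to π/6 ≈ 52%, far above
  the realistic 3–33%). Synapses are placed outside artifacts with the
  target count scaled to the artifact-free volume — which is precisely
  why artifact volume is discounted downstream.
* **Thickness**: per-case mean Normal(group mean, 0.38 mm) — control
  2.66 mm, disease 1.74 mm — with 3–5 sections × 3 measurements at
  0.05 mm measurement noise.
* **Semithin sections**: label images whose per-element pixel counts
  equal `round(f·n_pixels)` exactly (disks painted over background, the
  last disk trimmed), with the exact fractions stored as ground truth.
  Generating element fractions are Normal around the group means
  (control 7.17/0.50/3.28%, disease 5.86/0.35/3.71%).

**What the generator does not emulate.** Real stacks have between-case
biological variability in density beyond counting noise (the observed
across-case SD of ≈ 0.14 μm⁻³ exceeds the within-case sampling SD
produced here), anisotropic and non-ellipsoidal artifacts, z-axis
anisotropy of segmentation uncertainty, spatial correlation between
synapse size and position, and non-cap SAS shapes (perimeters of real
SAS of a given area are longer than a cap's, so absolute perimeter values
are not comparable — only their invariances and group contrasts are).
Passing tests therefore demonstrate correctness of the estimators and
pipeline plumbing under the stated model, not fidelity of any particular
biological claim.

## Problem sizes and determinism

The default synthetic study is 5 cases per group × 3 stacks of
5 × 5 × 5 μm with a 20% frame margin — chosen so a full pipeline run
takes seconds while each group still counts a few hundred synapses; the
published material used ≈ 10× larger stacks (260–824 μm³) with the same
estimator mathematics. Every stage seed derives from the single
configuration seed; identical configurations give bit-identical reports,
and the report records the seed and a configuration hash.

`scripts/acceptance.py --seed N --out results.json` recomputes the
worked examples, the shrinkage-convention check, the CSR calibration
(50 pattern seeds × 100-simulation envelopes), a full default study, and
the null calibration of the study-level U test, writing each value with
the problem size used.

## Known limitations

* The reduced-sample G/F estimators can be non-monotone and are NaN
  where no point survives the border condition (large r in small
  windows).
* The exact Mann-Whitney branch requires tie-free data; tied samples
  fall back to the corrected normal approximation regardless of size.
* The KS goodness-of-fit p-value after fitting parameters is the
  standard (slightly conservative) approximation.
* Rank-1 pointwise envelopes make no global-envelope claim.
* The projected-area union is exact only up to GEOS polygon precision;
  degenerate slivers are healed with a zero-width buffer.
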