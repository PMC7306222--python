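# Methods

## Problem and scope

Cymothoid isopods attach to fish with sickle-shaped dactyli whose outlines
carry no reliable landmarks. The package quantifies dactylus shape with
elliptic Fourier descriptors (EFDs) of the closed outline, compares
specimens in a PCA morphospace, measures per-group morphospace occupation
with convex hulls, and summarizes ontogenetic change as displacement
vectors between conspecific immature and adult scores. A synthetic hook
generator with known ground truth closes the loop: every claim about what
the morphospace axes mean is tested against generative parameters.

## Elliptic Fourier core

An outline is an implicitly closed polygon in y-up coordinates. EFD
coefficients are the exact Fourier integrals of the piecewise-linear curve
parameterized by arc length (chord-length parameterization), evaluated in
closed form per segment; the offsets A₀/C₀ are the arc-length centroid.
Arc-length parameterization was chosen over point-index parameterization
because it is robust to uneven digitization; its one consequence worth
knowing is that analytic shapes sampled by a different parameter acquire
slightly different coefficients (a 2×1 ellipse has first-harmonic semi-axes
1.8283/1.0730, not 2/1), and that Fourier synthesis followed by re-analysis
re-parameterizes the curve by its own arc length, so the synthesis/analysis
round trip agrees only to the truncation tail (≈2×10⁻³ per coefficient at
N = 20 for a default hook, decreasing with N). The analysis direction
itself is exact: it matches dense per-segment quadrature to <10⁻⁸ on random
polygons.

Normalization uses the first-harmonic ellipse: the phase θ of the start
point and the orientation ψ are removed, and all coefficients are divided
by the semi-major axis λ, leaving a₁ = 1, b₁ = c₁ = 0, with λ, ψ, θ kept
as metadata. Two discrete ambiguities must be fixed deterministically:

* which first-harmonic axis is "major" — resolved by maximizing λ over the
  four phase candidates θ + kπ/2;
* the residual 180° ("which end of the axis is the start") ambiguity —
  resolved by requiring the first significant even-harmonic coefficient,
  probed in the order c₂, d₂, a₂, b₂, c₄, ..., to be positive. For bent,
  hook-like outlines c₂ (the bending harmonic) decides; it is large and of
  constant sign across the whole generated hook family, so the rule is both
  transform-invariant for a single shape and continuous across a family of
  related shapes. (A rule keyed to a coefficient that crosses zero inside
  the family, e.g. a₂, makes normalized coefficients jump discontinuously
  mid-family and destroys PC interpretability — this failure mode is why
  the probe order starts at c₂.)

Outlines are canonicalized to counterclockwise orientation before analysis,
so d₁ > 0; mirrored (left-side) appendages are handled either on the
outline (reflection about the vertical centroid axis with traversal
reversal, an exact involution) or on coefficients,
(aₙ, bₙ, cₙ, dₙ) → (−aₙ, bₙ, cₙ, −dₙ) followed by re-normalization; the
two routes commute to 10⁻⁶.

## Outline preparation

* Canonical form: merge duplicate vertices, enforce ccw, start at the
  minimal (y, then x) vertex. The original digitization start points are
  unknowable and the normalization removes start-point dependence anyway;
  a fixed rule simply makes every intermediate artifact deterministic.
* Resampling: equal arc-length spacing (default 256 vertices) by linear
  interpolation; EFDs at 256 vs 512 vertices differ by <10⁻³.
* Proximal capping: dactylus drawings leave the articulation end concave
  or open; the open base is closed with a circular arc bulging away from
  the curve's interior. `arc_bulge` is the sagitta/chord ratio (0.5 =
  semicircle, the default reading of "rounded"); capping aborts with a
  diagnostic if the capped outline would self-intersect.
* Smoothing: closed-curve (¼, ½, ¼) vertex averaging, defaulting to 0
  iterations in the reproduction pipeline (setae were removed at the
  drawing stage in the source workflow, not numerically).

## Morphospace

The coefficient matrix holds one row per specimen, columns a₂..a_N,
b₂..b_N, c₂..c_N, d₁..d_N (4N−3 columns); a₁, b₁, c₁ are constants after
normalization and are excluded rather than carried as zero-variance
columns. PCA is on the column covariance matrix (coefficients are already
commensurate after normalization; a correlation PCA would inflate
near-zero harmonics). d₁ is kept: it varies (it encodes the first-harmonic
axis ratio). Loadings are sign-fixed so each component's
largest-magnitude entry is positive, making scores reproducible across
eigensolvers. Eigen-shapes are reconstructed from mean ± k·√λ_j·loading_j
with a₁ = 1, b₁ = c₁ = 0 reinserted.

Group occupation is the convex-hull area of a group's scores in a PC plane
(PC1×PC2 by default); hull overlap is convex-polygon intersection area.
Hull area operationalizes the qualitative "largest/smallest morphospace"
comparisons; fewer than 3 or collinear members give area 0 by convention.

Ontogenetic change: per species and appendage, displacement = adult score −
immature score in the PC plane (stage means if replicates exist). The
summary statistic R̄ = |mean of unit displacement vectors| ∈ [0, 1] is the
circular concentration of displacement directions: R̄ → 1 means a shared
trajectory, R̄ → 0 none. Unpaired species are skipped with a warning.

## Synthetic hooks

Construction: a circular-arc centerline of curvature κ and length L
(κL < 2π); width profile w(s) = (τL − w_min)(1 − s/L)^taper + w_min with
w_min = 0.04·L (hand-drawn hook tips are blunt at this scale); offset
curves both sides; a semicircular tip; a convex base cap (bulge 0.5); then
optional noise, resampling to 256 vertices and canonicalization. κ and τ
(max width / length) are exactly the two features the morphospace axes are
read as — degree of curvature and thickness — which is what makes the
parameter-recovery tests meaningful. Self-intersecting parameter
combinations (offset exceeding the curvature radius) are rejected.

Noise emulates redrawing error: Gaussian displacement along the local
outward normal, correlated over ~8 vertices (≈3% of the perimeter),
SD 0.005·L. Displacing along the normal rather than radially from the
centroid matters: centroid rays graze the outline of strongly curved hooks
and a varying tangential component folds the polyline.

Study design defaults (chosen once, as the package's definition of the
emulated study): 5 species per site × 3 sites × 2 stages × 2 appendages =
60 outlines; base (κ, τ) = (1.5/L, 0.28); site effects on (κ, τ): mouth
(+0.5, +0.05), gill (0, 0), external (−0.5, −0.05); stage effects:
immature (−0.25, −0.03), adult (+0.25, +0.03); species random effects
drawn once per species and shared by its four outlines, SD (0.15, 0.045) ≈
10% of the parameter means (the τ scale set so thickness contributes
meaningfully next to curvature, mirroring real hook data where both axes
carry large variance fractions), truncated at ±2.5 SD so every cell of the
design stays inside the generator's valid ranges for any seed. All
randomness flows through per-cell `SeedSequence` spawns, so datasets are
reproducible from one seed and independent of iteration order.

The generator emulates outline geometry only. It does not model allometry,
biomechanics, digitization pipelines of real drawings, or phylogenetic
covariance between species — so passing recovery tests shows the pipeline
measures what it claims on hook-like outlines, not that real cymothoid
dactyli follow this generative family.

## Independent estimator used as oracle

`estimate_curvature_thickness` deliberately avoids both the generator's
construction and the Fourier pipeline: the outline is rasterized (400 px),
the medial axis extracted, and the longest skeleton path taken as the
centerline; κ̂ is the curvature of the circumcircle through points at
15/50/85% of that path, and τ̂ is the maximal inscribed width divided by
the path length extended by the end radii (the skeleton retracts from tip
and base by roughly the local inscribed radius). On noiseless hooks κ̂ is
within 5% of truth over κL ∈ [0.5, 2.5]; τ̂ underestimates τ by a roughly
constant factor (skeleton-length bias) and is used only where monotone
agreement suffices.

## Trajectory contrast

The "shared vs no shared trajectory" logic is tested as a contrast: a
stage effect common to all species must concentrate displacement
directions (R̄ > 0.8 — species effects cancel in the adult−immature
difference), while per-species random stage-effect directions of the same
magnitude must disperse them. With 15 species the single-draw R̄ of random
directions has expectation ≈ 1/√15 ≈ 0.26 and substantial spread, so the
randomized scenario is summarized by the mean R̄ over 10 independent
randomizations, estimating the expectation of the statistic rather than
one draw of it.

## Sizes and numerics

Default problem sizes: 256-point outlines, N = 20 harmonics (sensitivity
across N ∈ {10, 20, 30} left as a config knob; harmonic-power cumulative
fractions support choosing N), 60-record designs, 30-hook recovery series,
10 randomization replicates. Doubles throughout; tolerances: normalization
invariance ≤10⁻⁶, quadrature agreement ≤10⁻⁶, nef round trip ≤10⁻⁶
relative, resampling perimeter conservation ≤0.5%. Degenerate inputs have
defined behavior: zero-area outlines and degenerate first harmonics raise;
rank-0 PCA returns all-zero eigenvalues; sub-triangle groups get hull area
0; unpaired species are skipped, not fatal.

## Known limitations

* EFDs are parameterization-dependent; comparisons are meaningful because
  every outline goes through the same arc-length convention.
* The 180° disambiguation is tailored to bent outlines; for families of
  near-symmetric shapes whose even harmonics all vanish the branch choice
  is arbitrary (though still transform-invariant per shape).
* Hull areas estimated from ≤5 points per group are noisy small-sample
  measures of occupation; no inferential statistics are attached, matching
  the qualitative character of the comparisons they operationalize.
* The medial-axis estimator assumes a single unbranched hook; it errors on
  other topologies rather than guessing.
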