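# hookmorph

Outline-based geometric morphometrics for the hook-shaped dactyli that
parasitic isopods (Cymothoidae) use to attach to their fish hosts. The
dactylus — the claw-like final element of a pereopod — varies with the
site of attachment (mouth, gill, external surface) and across ontogeny
(immature vs adult), and because these hooks carry almost no landmarks,
their shape is compared through closed-outline analysis rather than
landmark configurations.

`hookmorph` implements that workflow end to end:

1. **Digitization I/O** — Freeman chain-code files (`.chc`), x,y outline
   CSVs, binary raster masks (Moore-neighbor boundary tracing), normalized
   coefficient files (`.nef`), and specimen metadata tables.
2. **Outline preparation** — orientation/start-point canonicalization,
   equal-arc-length resampling, mirroring of left-side appendages, optional
   smoothing, and closure of the concave proximal articulation end with a
   convex circular cap.
3. **Elliptic Fourier descriptors** — for a closed outline parameterized by
   arc length t ∈ [0, T],

   x(t) = A₀ + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
   y(t) = C₀ + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T)

   with closed-form per-segment coefficients for polygons, normalized on
   the first-harmonic ellipse so that a₁ = 1 and b₁ = c₁ = 0 (size,
   rotation, translation and digitization start point removed).
4. **Morphospace** — covariance PCA of the coefficient matrix (columns
   a₂..a_N, b₂..b_N, c₂..c_N, d₁..d_N), eigen-shape reconstruction along
   any PC, per-group convex-hull occupation and hull overlaps, and
   ontogenetic displacement vectors (adult − immature per species) whose
   circular concentration R̄ = |mean unit vector| quantifies whether a
   shared developmental trajectory exists.
5. **Synthetic hooks** — a generator with two interpretable shape
   parameters, centerline curvature κ and relative thickness τ, emulating
   the comparative design (15 species, 5 per attachment site, 2 stages,
   2 appendages → 60 hooks), so the whole pipeline is testable without any
   external data and the PC axes can be validated against ground truth.

## Worked example

Simulate the full study design, run the pipeline, and check that the
morphospace axes recover the generative parameters:

```sh
hookmorph simulate --out-dir demo --seed 1
```

prints

```
PC1 91.4%, PC2 5.8% of variance; 60 specimens
{
  "corr_pc1_kappa>0.95": true,
  "corr_pc1_tau>0.95": true,
  "rbar_coherent>0.8": true,
  "rbar_random_mean<0.3": true
}
```

meaning: on the 60 synthetic hooks PC1 and PC2 absorb almost all shape
variance; a series varying only curvature is recovered by PC1 with
|r| > 0.95, as is a series varying only thickness; a stage effect shared by
all species produces tightly aligned adult−immature displacement vectors
(R̄ ≈ 0.99), while per-species random stage effects scatter them
(mean R̄ ≈ 0.2) — the operational version of asking whether a common
ontogenetic trajectory exists. `demo/` then contains the fixture bundle
(`hooks.chc`, `hooks.nef`, `metadata.csv`, `truth.csv`), the morphospace
tables (`variance.csv`, `scores.csv`, `loadings.csv`, `hulls.csv`,
`hull_overlaps.csv`, `ontogenetic_vectors.csv`, eigen-shape outlines, and
per-appendage panel tables), and `recovery_report.json`. For example

```
component,eigenvalue,percent_variance,cumulative_percent
PC1,0.009968694035632334,91.3731994946117,91.3731994946117
PC2,0.0006296005108956102,5.770927754261733,97.14412724887343
```

Real data follow the same route from files:

```sh
hookmorph efd --chc demo/hooks.chc --out-nef out.nef --out-csv coeffs.csv
hookmorph pca --nef out.nef --metadata demo/metadata.csv --out-dir morpho
hookmorph report --scores morpho/scores.csv --out morphospace.png
```

Or from the library:

```python
from hookmorph import DesignSpec, generate_dataset, ontogenetic_vectors
from hookmorph.pipeline import analyze_records

records = generate_dataset(DesignSpec(seed=1)).records
result = analyze_records(records, n_harmonics=20)
print(result.variance_fraction[:2])          # leading variance fractions
vectors, summary = ontogenetic_vectors(result)
print(summary["rbar"])                       # trajectory concentration
```

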