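# necrofract

Fractal analysis of intratumoral necrosis patterns on post-contrast
T1-weighted MRI, and what those patterns mean for glioblastoma outcome.

Necrosis is a hallmark of glioblastoma: a dark, irregularly shaped region
inside the contrast-enhancing mass. Its geometry is hard to summarize with
ordinary measurements, but two fractal statistics capture it well:

* **Box-counting fractal dimension (FD)** — cover the binarized necrosis
  pattern with grids of boxes of side ε and count the boxes N(ε) that
  contain foreground; FD is the negated least-squares slope of
  ln N(ε) vs ln ε. Rougher, more space-filling patterns score higher.
* **Lacunarity (λ)** — the squared coefficient of variation (σ/μ)² of the
  per-box foreground masses, averaged over box sizes and grid placements.
  Gappier, more heterogeneous patterns score higher.

The package implements the full analysis chain as a tested library with a
CLI, exercisable end to end on synthetic phantoms with known ground truth:

1. **Segmentation** (`necrofract.segmentation`) — semi-supervised necrosis
   delineation inside a tumor mask by harmonic label propagation: pixels
   form a graph with Gaussian intensity affinities
   w_ij = exp(−(I_i−I_j)²/σ²), seed pixels are clamped (1 = necrosis,
   0 = enhancing tumor), and unlabeled pixels solve the clamped
   graph-Laplacian system f_u = −L_uu⁻¹ L_ul f_l; the mask is the field
   thresholded at 0.5.
2. **Fractal features** (`necrofract.fractal`) — FracLac-style scan
   protocol: box sizes from 2 px up to 45% of the cropped region's larger
   side, twelve grid placements (one aligned, eleven seeded random
   offsets), FD and λ per grid then averaged; per-patient features are
   means over necrosis-bearing slices.
3. **Survival** (`necrofract.survival`) — Kaplan–Meier curves, log-rank
   tests, and univariate/multivariate Cox proportional-hazards models
   (Efron ties, Wald CIs) for patients dichotomized at fixed cutoffs
   (FD < 1.56, λ > 0.46, age ≥ 50, KPS < 80, volume ≥ 50 cm³, subtotal
   resection); FD and λ enter separate adjusted models because they are
   strongly anticorrelated.
4. **Gene screen** (`necrofract.gene_screen`) — genes with Pearson r > 0.3
   against patient lacunarity, plus hypergeometric gene-set enrichment
   (Benjamini–Hochberg across sets) against user-supplied GMT files.
5. **Synthetic data** (`necrofract.synthetic`) — Sierpinski carpets and
   random Cantor dust with known dimension, tumor/necrosis intensity
   phantoms with returned truth masks, survival cohorts with planted
   hazard ratios, and expression matrices with planted correlations.

## Worked example

A fully synthetic 60-patient run — phantoms are generated, segmented and
measured; a cohort with hazard ratio 2.0 planted on both dichotomized
fractal features is simulated around the measured values; survival tables
and the gene screen are written as CSVs:

```bash
necrofract demo --seed 1 --out results/cohort_run
# demo complete; 14 artifacts in results/cohort_run
# FD-lacunarity correlation: r=-0.833 (p=1.5e-16)
```

The negative correlation mirrors the geometry: punching gaps into the
necrotic core removes mass (FD falls) while making the pattern lumpier
(λ rises). In `results/cohort_run/univariate.csv` the planted effects
surface exactly where they should, and nowhere else:

```
covariate endpoint     p    hr  ci_lower  ci_upper
   fd_low      pfs 0.000 3.085     1.721     5.529
   fd_low       os 0.000 5.422     2.700    10.888
 lac_high      pfs 0.001 2.483     1.434     4.301
 lac_high       os 0.000 6.060     2.958    12.417
```

(the clinical covariates — age, KPS, volume, resection, adjuvant therapy —
all sit at p > 0.3, as simulated). The univariate hazard ratios exceed the
per-feature planted 2.0 because the two high-risk groups largely coincide,
so each absorbs part of the other's effect; the multivariate tables show
the adjusted estimates. `screened_genes.csv` and `enrichment.csv` hold the
lacunarity-correlated genes and their gene-set enrichment; the planted set
ranks first at q < 1e-30 while random sets sit near q = 0.85.

The same stages are scriptable: `analysis/01_fractal_validation.py`
(estimator oracles), `02_segmentation_evaluation.py` (Dice vs noise),
`03_cohort_survival.py` (the cohort run above), `04_gene_screen_power.py`
(screen power vs planted correlation strength). Real data run through
`necrofract run --config cfg.yaml` with a slice manifest (PNG or
single-slice NIfTI images/masks) and a clinical cohort CSV; see
`necrofract.pipeline.InputPaths`.

## Notes

The default scan protocol reproduces a published convention, not a
ground-truth estimator: on finite prefractal fixtures its least-squares
slope is biased low at the smallest and largest box sizes (see
`docs/methods.md`). Absolute lacunarity values depend on the variant
(empty-box handling, normalization); comparisons are meaningful within one
protocol, not across software.
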