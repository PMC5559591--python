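# Methods

## Scope and data model

The package analyzes 2D binary necrosis patterns inside tumor masks on
post-contrast T1-weighted MRI slices. Per slice: an intensity image, a
tumor ROI mask (given), and a necrosis mask (given or segmented). Per
patient: slice-averaged fractal features joined to clinical covariates and
PFS/OS outcomes. Coordinates are row-major, 0-based, pixel-centered.

## Harmonic segmentation

Necrosis is delineated semi-supervisedly. Pixels inside the tumor mask
form a graph (8-connectivity by default) with Gaussian intensity
affinities w_ij = exp(−(I_i−I_j)²/σ²). The bandwidth σ defaults to the
standard deviation of within-mask neighbor intensity differences — a
scale-free choice that adapts to each image's contrast; on a constant
image it falls back to 1.0, where all weights are exp(0) = 1 anyway. Seeds
(necrosis = 1, tumor = 0) are clamped and the remaining pixels take the
harmonic extension, the solution of L_uu f_u = W_ul f_l obtained by sparse
LU; the residual is checked against 1e−8 so the result is interchangeable
with a dense solve (verified on all graphs ≤ 50 nodes in the tests). By
the maximum principle the field lies in [0, 1]; values are clipped against
~1e−12 numerical overshoot. The necrosis mask is the strict cut f > 0.5,
ties to background — a symmetric two-class rule with a deterministic
tie-break. Components containing no seed are an error naming the component
size rather than a silent all-background assignment.

Quantile auto-seeding (darkest 10% of within-mask intensities → necrosis
seeds, brightest decile → tumor seeds) replaces the interactive scribbles
a radiologist would supply; on two-band phantoms it seeds both classes
correctly by construction. The graph construction itself (features,
connectivity, σ) is this package's choice; no byte-equivalence with any
prior interactive implementation is claimed.

## Box-counting protocol

The scan follows the FracLac convention for necrosis masks:

* analysis region: the necrosis pattern cropped to the tumor ROI bounding
  box (the tumor acts only as the border; foreground is necrosis alone);
* box sizes: 12 unique integers log-spaced from 2 px to
  floor(0.45 × larger side of the crop). The 45% limit is read as a
  fraction of the linear extent; an areal reading would allow boxes larger
  than the image;
* grids: 12 placements — grid 0 anchored at the crop origin, the rest at
  seeded pseudo-random offsets uniform over [0, ε)² per size; partial edge
  boxes participate with their true (smaller) capacity, and masses are raw
  pixel counts;
* FD: per grid, the negated least-squares slope of ln N(ε) vs ln ε over
  sizes with N > 0; the slice FD is the mean over grids;
* lacunarity: per (ε, grid), λ = (σ/μ)² of box masses with empty boxes
  included and population variance (λ is a moment ratio of the box-mass
  distribution, not a sample estimate); averaged over sizes, then grids;
* patients: unweighted mean over necrosis-bearing slices; slices with
  empty necrosis are skipped with a log entry, not counted as zeros.

Explicit `box_sizes` override the schedule for validation scans (e.g.
powers of 3 on base-3 fixtures).

### Known bias of the default protocol

On exactly self-similar fixtures the estimator is exact in the scaling
regime: the order-4 Sierpinski carpet scanned aligned at sizes {3, 9, 27}
returns log 8/log 3 to machine precision, and random Cantor dust (b = 3,
levels = 4) recovers D = log(9p)/log 3 within ~0.01–0.03 averaged over
seeds. Under the default protocol, however, the same 81-px carpet reads
≈ 1.70: a finite-order prefractal has no structure below 1 px, so at
ε = 2 it is locally space-filling (N = 1320 vs the power law's 1103), and
at ε ≥ 28 the lattice saturates (N = 9 vs 4.6); the global least-squares
slope therefore mixes dimension-2 end behavior into the fit. The bias
shrinks only logarithmically with carpet order (1.70 → 1.76 → 1.79 for
orders 4–6). This is a property of finite fixtures under the published
protocol, not an implementation error; analyses should compare FD values
obtained under one protocol, never across protocols or software.
Similarly, absolute λ depends strongly on the variant (empty-box
inclusion, gliding vs fixed grids, normalization); values here are
internally consistent but not comparable to other software beyond order of
magnitude.

## Synthetic phantoms

`make_tumor_phantom` emulates one post-contrast T1 slice. The tumor is a
star-convex region r(θ) = r₀(1 + Σ a_k cos(kθ + φ_k)), k = 2..9, with
amplitudes a_k = 0.12 · β/(1+β) · k^(−β/2): the spectral exponent β shapes
how quickly harmonics decay, and the β/(1+β) envelope makes β = 0 an exact
disk. The necrotic core is the same boundary radially scaled by
√(necrosis_fraction) (radial scaling by s scales a star-convex area by
s²), and `n_holes` disks inside the core are re-brightened to rim
intensity and removed from the truth mask. Intensity bands are rim 0.8,
necrosis 0.2, background 0.05 on [0, 1] with additive Gaussian noise
σ = 0.05 — a bright enhancing rim around a dark core with comfortable
contrast for quantile seeding. Cohort phantoms vary β ∈ [0.5, 4],
necrosis fraction ∈ [0.2, 0.5] and above all the number (0–14) and radius
(2–8 px) of holes: hole-riddled cores lose box-counting dimension and gain
lacunarity, which is the mechanism behind the cohort-level negative FD–λ
correlation (r ≈ −0.8 to −0.9 on 60 phantoms).

What the phantoms do **not** emulate: 3D anatomy and slice correlation,
MRI physics (bias fields, partial volume), multifocal or non-star-convex
tumors, and FD/λ value scales matched to any particular scanner or
cohort. Passing tests demonstrate estimator and pipeline correctness on
known geometry, not clinical performance.

## Synthetic cohorts

Death time is exponential with hazard
h = h₀ · hr_fd^[FD<cut] · hr_λ^[λ>cut]; progression is the minimum of
death and an independent Exp(1.5 h) progression process, so PFS ≤ OS and
both endpoints follow exact proportional hazards at the planted ratios
(the minimum of independent exponentials is exponential — an earlier
"progression plus residual" construction was rejected because its OS
hazard was non-proportional and inflated fitted ratios). Censoring is one
uniform U(0, u) time per patient applied to both endpoints
(administrative censoring), with u solved by bracketing so the expected
censored fraction matches the requested rate. Defaults: baseline hazard
1/400 per day (reference-group median OS ≈ 277 days), censor rate 0.2,
n = 60 — values a glioblastoma cohort of this size would plausibly show.
Clinical covariates are drawn from simple seeded distributions spanning
typical values (age N(50, 12) clipped to 19–76, KPS 50–100 with median
70, log-normal volume with median 45 cm³, GTR probability 0.56, adjuvant
therapy probability 0.91) and carry no planted effect.

Calibration under these conditions (recomputed by `scripts/acceptance.py`
and the test suite): log-rank size at α = 0.05 within [0.01, 0.10] over
500 null cohorts; Cox hazard-ratio recovery for a planted 2.0 within
[1.6, 2.5] at n = 500; the 4-subject Cox coefficient matches a brute-force
grid maximization of the Efron partial likelihood to 1e−4.

## Cutoffs and the median-split mode

Package defaults dichotomize at the published constants (FD < 1.56,
λ > 0.46, age ≥ 50, KPS < 80, volume ≥ 50 cm³), with inequalities strict
exactly as printed: boundary values land in the low-risk group for the
fractal features. Because synthetic λ lives on the empty-box-CV² scale
rather than the scale of those constants — and because the published
fractal cutoffs sit essentially at that cohort's medians — the synthetic
demo dichotomizes at its own cohort medians (the optional median-split
mode, off by default for real data). The planted hazards are applied to
the same median-defined groups, so the demo measures genuine recovery,
not a scale coincidence. No multiplicity adjustment is applied to the
univariate table, matching the analysis convention it reproduces.

Demo-recovery measurements average the log hazard ratio over 5 seeded
60-patient cohorts: a single cohort of that size carries ~2× sampling
noise in the hazard ratio (se(log HR) ≈ 0.32), and a 30-replicate check
confirmed the pipeline estimate is unbiased (mean log HR 0.684 vs planted
0.693).

## Gene screen and enrichment

Per gene, the sample Pearson correlation with patient lacunarity;
selection is strictly r > 0.3, positive correlations only (an
absolute-value switch exists because the rule's phrasing is ambiguous in
the source analysis; positive-only is the default reading). Expression
values are used as provided; a log2(x+1) switch defaults off.
Zero-variance genes are excluded with a log entry. At n = 32 patients the
analytic null tail P(r > 0.3) ≈ 0.048 sets the false-selection floor —
the screen deliberately has no p-value filter. Planted-truth power under
the default conditions (ρ = 0.6, 100 planted among 1000, 32 patients):
recall ≈ 0.99, false rate ≈ 0.05, averaged over 20 seeds.

Enrichment replaces an external annotation service with a one-sided
hypergeometric upper-tail test against user-supplied GMT sets intersected
with the declared universe, Benjamini–Hochberg adjusted across sets, rows
ordered by (q, name) for determinism.

## Reproducibility machinery

One master seed drives every stochastic stage through per-operation
streams derived via `SeedSequence(seed, spawn_key=crc32(tag), ...)`, so
adding a generator call in one stage never shifts another stage's stream,
and a patient index in the key gives each phantom a private stream. Two
runs under one seed produce byte-identical CSV/TSV outputs (asserted in
the tests); `report.json` records the config hash, seed and library
versions needed to reproduce a run. Skipped slices and patients are
logged and listed in the report — no silent exclusions.

## Problem sizes

Default analysis sizes were chosen to keep every property measurable with
comfortable statistical margins at interactive runtimes: phantom canvases
96–128 px, 60-patient demo cohorts, 500-replicate null calibration at
n = 100, recovery at n = 500, 20-seed averages for Monte-Carlo
properties.

## Limitations

* 2D only; no volumetric box counting or 3D propagation.
* The λ variant (fixed-grid, empty boxes included, (σ/μ)²) is one of
  several in use; alternatives (gliding-box, 1+CV²) would need a new
  variant behind the same scan machinery.
* Cox models assume proportional hazards; no diagnostics, time-varying
  covariates or competing risks.
* The gene screen is a marginal correlation filter; it makes no causal or
  multivariate claim.
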