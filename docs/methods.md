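# Methods

This note documents the statistical methods implemented in `wacalib`, the
parameter defaults and their rationale, the design of the synthetic-data
generator, and the package's limitations. Every empirical number quoted in
the package's documentation was computed by the code in this repository on
synthetic data; no result is reported that the code did not produce.

## 1. Data model

- **Abundance matrix** — samples × taxa, in one of four bases: `density`
  (cells/ml), `biovolume` (µm³/ml) or their relative (row-normalized)
  forms. All calibration statistics operate on a relative basis; the
  `abundance_basis` is carried through to the coefficient table so results
  from different representations are never silently mixed.
- **Environment table** — sites × variables in original units, with a
  per-variable transform registry (`none`, `log` = base-10, `sqrt`)
  applied before any statistic. Variables that can legitimately be zero
  (e.g. chlorophyll, nitrate) receive a log offset defaulting to half the
  smallest positive observed value; the offset is recorded and used
  symmetrically by the inverse transform. Nutrient ratios N:P, N:Si and
  P:Si are molar (molar masses N 14.0067, P 30.973762, Si 28.0855 g/mol),
  with nitrogen and silica read in mg/L and TP in µg/L by default.
- **Core stratigraphy** — dated intervals × taxa, rows summing to one,
  strictly monotone chronology.

## 2. Taxon–environment coefficients

For each taxon present in more than 5 samples (10 for the smoother tests)
and each transformed variable:

- **Linear**: the OLS slope sign, reported only when the Pearson
  correlation is significant at P < 0.05, else 0.
- **Gaussian (unimodal)**: a quadratic Poisson-family GLM
  log E[y] = b₀ + b₁x + b₂x², the canonical Gaussian response model. With
  b₂ < 0 the optimum is the vertex −b₁/(2b₂) clipped to the observed
  range; otherwise the argmax lies on a range boundary. A paired t-test on
  absolute residuals versus the linear fit flags taxa whose unimodal fit
  is significantly better.
- **Weighted averaging**: the abundance-weighted mean of gradient values.

Optima are rescaled to integers 0–10 over the observed gradient range
(rounding half up). Season and lake specificities are the taxon's share of
total abundance per category × 10, rounded half up.

**Smoother-based TP tests.** A taxon's response to TP is tested with a
penalized cubic B-spline (6 basis functions, quantile-placed knots,
second-difference penalty, smoothness chosen by GCV on a 17-point log-λ
grid). The statistic is the deviance explained (1 − RSS/TSS); significance
comes from permuting TP across samples with the +1-corrected Monte Carlo
p-value p = (1 + #{perm ≥ obs}) / (n_perm + 1), default n_perm = 199.
Crucially, **λ is re-selected by GCV for every permutation**: fixing the
observed data's λ would break exchangeability (the observed statistic
benefits from its own selection step) and makes the test anti-conservative
— we measured ~10% rejections at nominal 5% with fixed λ versus the
nominal rate with per-permutation selection. Because row permutations
leave BᵀB unchanged, the per-λ normal-equation inverses are precomputed
once, making per-permutation re-selection cheap. The conditional test
(TP given alkalinity) uses the added deviance of a TP spline over an
alkalinity-only spline, permuting TP while the alkalinity design and its
penalty stay fixed.

## 3. Weighted-averaging transfer function

Optima uₖ and tolerances tₖ are abundance-weighted means and standard
deviations of the transformed gradient. The initial sample inference is
the weighted mean of the optima with weights yᵢₖ/tₖ² (tolerance
downweighting, default on) or yᵢₖ; tolerances are floored at one tenth of
the gradient's standard deviation so single-occurrence taxa (tolerance 0)
cannot dominate. Inverse deshrinking regresses the observed gradient on
the initial inferences; `deshrink="none"` is available for comparison.
Leave-one-out jackknifing refits the complete pipeline — coefficients,
floor and deshrinking — per held-out sample and reports r² and RMSEP in
transformed units; by construction RMSEP(jack) ≥ RMSE(apparent).

Predictions on new assemblages renormalize each row over the model's taxa
and report the retained fraction as `coverage`; samples sharing no taxa
with the model get a missing inference, never a silent extrapolation.

**MAT comparator.** Squared chord distance on relative abundances,
inference = mean gradient value of the k = 5 nearest training samples;
ties with the k-th distance are all included.

## 4. Spatial diagnostics

- **Empirical variogram**: binned semivariance γ(h) = mean squared
  difference / 2, up to half the maximum inter-site distance (the usual
  reliability cutoff). Theoretical models (exponential, spherical,
  Gaussian: γ(h) = nugget + sill·(1 − ρ(h))) are fitted by weighted least
  squares with Cressie-style weights √(count)/model; a grid search is the
  flagged fallback if the optimizer fails.
- **Randomization test**: the gradient is replaced by Gaussian random
  fields sharing its fitted variogram (exact simulation via Cholesky
  factorization of the full covariance matrix), the model is refit per
  simulation, and the real model's r² is located in the null distribution
  (percentile and +1-corrected p). A model whose skill merely reflects
  spatial structure lands inside the null.
- **rne (random / neighborhood / environment) test**: leave-one-out r²
  is recomputed while deleting, per test sample, (a) all training sites
  within a geographic radius, (b) the same *count* of sites nearest in
  gradient value, (c) the same count at random. A geographic curve falling
  below the random curve is the signature of spatial autocorrelation
  propping up the model; on unstructured data the curves coincide.

## 5. Ordination

Species data are centered (optionally Hellinger-transformed), predictors
standardized, exactly collinear predictors dropped deterministically in
input order. RDA = SVD of the fitted values of the multivariate regression
of species on predictors; residual SVD gives unconstrained axes; fractions
are of the original total species sum of squares, so conditioned +
constrained + unconstrained = 1. Site scores are weighted sums of species
scores (site = Y_centered · V), which makes passive projection of fossil
assemblages a plain matrix product after renormalizing over shared taxa
and centering with the *training* means. Marginal permutation tests
permute one variable's values (statistic: variance constrained by that
variable alone). Variance partitioning reports a focal variable's total
fraction (RDA on it alone) and unique fraction (constrained fraction after
residualizing both blocks on the conditioners, still relative to the
original total). The implementation is cross-checked against the R package
`vegan` in the test suite.

## 6. Reconstruction diagnostics

DI-TP error bands are inference ± jackknife RMSEP on the transformed scale
and back-transformed (hence asymmetric in µg/L). λR is the axis-1
constrained fraction of an RDA of the core species on the DI-TP series;
λP is the axis-1 PCA fraction; λR ≤ λP always, and a ratio near 1 means
the reconstruction tracks the core's main compositional gradient. The
DI-TP vs PCA-axis-1 correlation is reported signed (axis orientation is
arbitrary) and as a magnitude.

## 7. Synthetic-data generator

The generator reproduces exactly the statistical structure the calibration
assumes, nothing more:

- **Environment**: each variable is a Gaussian random field over the site
  coordinates with a chosen variogram (default TP: mean 0.55, nugget 0.01,
  sill 0.10 on log₁₀ µg/L, exponential with 300 km range over a 1000 km
  square — a plausible large-survey configuration: mean ≈ 3.5 µg/L,
  marginal sd ≈ 0.33 log units). Cross-variable correlation is induced by
  linear mixing with a symmetric matrix square root. Fields are simulated
  exactly by Cholesky factorization — O(n³), appropriate at survey scale
  (hundreds of sites), not for rasters.
- **Species**: unimodal responses c·exp(−(x−u)²/2t²) along one transformed
  gradient; counts multinomial with 400 valves per sample by default (the
  conventional diatom count), with Poisson and negative-binomial options
  for absolute-abundance designs.
- **Cores**: multinomial draws along a prescribed trajectory; the default
  scenario is a 26-interval record (1700–2010) with baseline log-TP 0.45,
  a ramp to +0.40 over 1900–1950 and recovery by 1990.

Design decisions (made while designing the generator, before freezing any
test): pool optima span ±2 marginal standard deviations of the gradient —
optima beyond the sampled gradient make the WA estimate intrinsically
truncated (an estimator property, not an implementation defect), so
interior optima are the standard recovery-benchmark design; tolerances are
uniform on [0.10, 0.30] log units (⅓ to 1 gradient standard deviation) so
every taxon turns over appreciably — a niche broader than the gradient
yields a nearly flat response and a centroid-shrunk WA optimum whatever
the estimator.

What the generator deliberately does **not** emulate: plankton seasonality
and succession, taxonomic error, differential preservation, sediment
mixing or chronological uncertainty. It contains only the structure the
statistics rest on, so failures in the tests indicate implementation
errors rather than ecological mis-specification.

## 8. Numerical choices

- Exact GRF simulation via Cholesky with a 10⁻¹⁰ jitter on the diagonal.
- Deshrinking and all regressions via `numpy.polyfit`/`lstsq` (SVD-based).
- Unimodal GLM fits via `statsmodels` IRLS with a linear fallback on
  non-convergence (flagged, never silent).
- Permutation p-values always use the +1 correction, so p > 0 and the
  tests are exact for any number of permutations.
- All seeds flow through `numpy.random.Generator`; every stochastic
  routine is bit-reproducible given a seed.

## 9. Limitations

- One-gradient WA: no WA-PLS or multi-gradient calibration.
- The randomization test defaults to apparent r² (cross-validated r² is
  available but slow for large n_sim).
- Cholesky-based simulation limits fields to a few thousand sites.
- The λR/λP diagnostic is computed on the core's own species matrix; the
  published variant projecting onto the training ordination is available
  via `passive_project` but not folded into the ratio.
- Indicator values are reported on the observed gradient range of the
  training set; they are not transferable between training sets with
  different ranges.
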