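# Methods

## Model

`dtameta` pools diagnostic 2×2 tables with the bivariate
binomial–normal random-effects model.  Trial *i* contributes two
binomial observations — TPᵢ out of n₁ᵢ diseased and TNᵢ out of n₂ᵢ
non-diseased — whose success probabilities are the inverse-logits of a
latent pair (aᵢ, bᵢ) drawn from N₂(μ, Σ).  μ = (μ₁, μ₂) carries the
population mean logit sensitivity and specificity; Σ the between-study
covariance, whose correlation is typically non-zero because implicit
positivity thresholds and case-mix vary across studies.  The exact
binomial within-study likelihood makes continuity corrections
unnecessary for the model itself; corrections only enter the
descriptive statistics (below).

### Likelihood and quadrature

The marginal likelihood integrates the random effects numerically with
**adaptive** tensor-product Gauss–Hermite quadrature (default 25 nodes
per dimension).  For each study a damped Newton search locates the mode
of the integrand (binomial kernels × normal prior) and its curvature;
the Hermite grid is recentred and rescaled there.  Adaptivity matters:
a large trial's likelihood can be an order of magnitude sharper than
the prior, and a prior-centred rule then sees almost none of the
integrand's mass — on the packaged dataset a non-adaptive rule at 25
vs 51 nodes disagreed in the third decimal, while the adaptive rule
agrees to ~1e−12 and matches dense-grid 2-D integration to better than
1e−5 on small test problems.  Σ = 0 is handled exactly (the integral
collapses to the binomials at μ).

### Optimisation and uncertainty

ML runs in unconstrained coordinates — (μ₁, μ₂, log σ₁, log σ₂,
atanh ρ) by default, a log-diagonal Cholesky alternative for
cross-checks — via L-BFGS-B with three-point numeric gradients, from
moment-based starting values (mean and noise-corrected covariance of
the corrected logits).  Up to five deterministically jittered restarts
plus a Nelder–Mead polish guard against stalls; convergence failures
raise an error carrying the best point.  `cov(μ̂)` is the μ-block of
the inverse of the full central-difference Hessian, so variance-component
uncertainty propagates into the means.  95% intervals are Wald:
logit scale for proportions, log scale (delta method) for PLR, NLR and
DOR.  The full model requires ≥ 4 trials (5 parameters).

### SROC and AUC

The bivariate moments map algebraically to the HSROC (Rutter–Gatsonis)
parameters after re-expressing the second axis as x = logit FPR
(m₂ = −μ₂, s₁₂ = −σ₁₂):

    β = ½ ln(s₂²/s₁²),   Λ = √(s₂/s₁)·μ₁ − √(s₁/s₂)·m₂,
    σθ² = (s₁s₂ + s₁₂)/2,   σα² = 2(s₁s₂ − s₁₂)  (truncated at 0),

with the summary curve sens(x) = expit(Λe^(−β/2) + xe^(−β)).  The AUC
integrates sensitivity over FPR by trapezoid on 2001 uniform points
over the full (0, 1) range — endpoints filled by the curve's limits —
matching the convention of the GLMM-based DTA software family.  A
restricted "observed FPR band" integration with width normalisation,
and an alternative regression-of-logits curve, are available but off by
default.

## Descriptive statistics and diagnostics

- **Continuity correction**: 0.5 added to all four cells of any table
  containing a zero (`zero_cells_only`, the default; `all_cells` and
  `never` available).  Applied to per-study metrics, Q/I², Spearman and
  Deeks inputs — not to the GLMM.
- **Q and I²** are computed separately for logit Se and logit Sp
  against the fixed-effect inverse-variance mean;
  I² = max(0, (Q−df)/Q)·100.
- **Threshold effect**: Spearman rank correlation (average ranks) of
  logit Se vs logit FPR; two-sided p from the t approximation on n−2
  df (exact permutation enumeration available for n ≤ 9); flagged when
  ρ > 0.6 with p < 0.05.
- **Deeks' asymmetry test**: WLS of ln DOR on 1/√ESS with weights ESS,
  where ESS = 4n₁n₂/(n₁+n₂) uses raw arm sizes; two-sided t-test of
  zero slope, conventional 0.10 significance threshold.

## Robustness analyses

- **Leave-one-out** refits the model n times; the verdict is "stable"
  when every reduced-set pooled Se and Sp stays inside the full fit's
  95% CIs.
- **Outlier detection** flags trial *i* when
  dᵢ = zᵢᵀ(Σ̂ + Wᵢ)⁻¹zᵢ > χ²₂(0.95), zᵢ the corrected logit pair minus
  μ̂.  Wᵢ is evaluated at the *fitted* pooled probabilities,
  Wᵢ = diag(1/(n₁ᵢ p̂(1−p̂)), 1/(n₂ᵢ q̂(1−q̂))) — a Pearson-type
  standardisation.  Using observed corrected counts instead (available
  via `within="observed"`) lets a tiny trial with perfect cells assign
  itself a huge variance and mask its own extremeness, which is exactly
  the pattern outlier screening should catch; on the packaged data the
  model-based form flags the two perfect-accuracy trials plus three
  other extreme tables, the observed form only one study.
- **Subgroups** refit the full model per level of a metadata column;
  levels with < 4 trials fall back to univariate DerSimonian–Laird
  pooling of each logit axis (via statsmodels) and report no AUC
  (printed as N.A.), since the five-parameter model and a summary
  curve are not identifiable there.  A single-trial level reports its
  own estimates with Wald intervals.

## Synthetic-data generator

`simulate_studies` draws exactly from the assumed hierarchy: latent
logit pairs from N₂(μ, Σ), total sizes and diseased fractions from
configurable laws, binomial cells.  Defaults — totals uniform on
[20, 300], diseased fraction uniform on [0.3, 0.7] — echo the span of
the packaged trials (18–326 subjects).  A root seed spawns per-study
and per-replicate substreams, so any replicate reproduces in
isolation.  The generator emulates study-level sampling only: it does
not model selective publication, correlated thresholds within
articles, imperfect reference standards or covariate-driven accuracy,
so passing recovery tests demonstrates estimator correctness under the
model, not robustness to those real-data violations.

`parameter_recovery` repeats simulate→fit and reports bias, RMSE and
95% CI coverage for μ and the variance components.  The calibration
test uses 100 replicates of 30 trials of 50–300 subjects at
μ = (1.15, 1.52), Σ = [[0.3, −0.1], [−0.1, 0.3]] — a regime shaped
like the packaged dataset — and asserts |bias(μ)| < 0.1 with coverage
in [0.90, 0.99].

## The packaged dataset

The fixture transcribes the 30-trial exosomal miR-21 collection with
one documented correction: the source table's two middle count columns
are transposed relative to its printed header (TP, FP, FN, TN in
reality).  Both the pooled fit and the source's own "PPV > 75% in 23 of
30 trials" statement confirm the transposition; details in
`src/dtameta/fixtures/README.md`.  Subgroup labels (ethnicity, cancer
group, specimen group, pancreatic flag) are stored as columns because
the source does not enumerate memberships; the pancreatic-cancer
summary corresponds most closely to the PC/PDAC-labelled subset.

Two reported diagnostics of the source resist reproduction from its
own tables and are documented rather than matched: the Deeks p-value
(the canonical test gives p < 0.001 on these 30 tables — several tiny
trials have extreme DORs, a genuinely asymmetric funnel) and the
pancreatic subgroup's specificity/AUC (84%/91% printed; the model
gives ~80%/87% under every defensible membership).  The corresponding
acceptance-suite tests are left failing by design; all headline pooled
quantities, the exclusion refit and the ethnicity subgroup reproduce
within tolerance.

## Numerical choices and limitations

- Quadrature nodes default to 25/dimension; tests cross-check 15/25/51.
- Wald z = 1.96 at 95% throughout; no profile or bootstrap intervals.
- No AUC confidence interval (bootstrap is future work).
- σα² truncation at 0 emits a warning; a zero between-study variance on
  either axis makes the HSROC mapping degenerate and raises instead of
  silently switching to a symmetric curve.
- Ties in the Spearman screen use average ranks; the t-approximation p
  is anti-conservative below n ≈ 10, where the exact option applies.
- Meta-regression with continuous covariates and Bayesian fitting are
  out of scope; subgroups are handled by stratified refitting only.
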