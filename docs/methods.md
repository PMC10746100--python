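# Methods

This note records the statistical model, every tunable parameter with
its default and rationale, the scope of the synthetic-cohort generator,
and the numerical choices made in the implementation.

## Outcome and conventions

- **%BMIL** is the signed percent BMI change,
  `100 * (BMI_final − BMI_baseline) / BMI_baseline`. Weight loss is
  negative; "greater loss" always means "more negative %BMIL". A
  `convention="loss_positive"` flag on phenotype input flips the sign on
  read for data recorded the other way.
- **Diet arms** are labeled `MHP` (moderately high protein) and `LF`
  (low fat). The interaction model codes the reference arm as 0
  (default `MHP`); sex is coded female = 0.
- Methylation is a samples × probes matrix of beta values in [0, 1]
  (`strict_beta=True` enforces the range; the default only requires
  finite values, since preprocessed matrices sometimes leave the unit
  interval slightly).

## Pipeline stages

### 1. SD filter

Probes with sample standard deviation (ddof = 1) **strictly greater
than** `sd_min = 0.1` are kept. Near-constant probes cannot carry a
reproducible association and inflate the multiple-testing burden. The
filter is a strict inequality; a probe with SD exactly 0.1 is dropped.

### 2. Per-arm Spearman screen

For each surviving CpG and each diet arm separately, the Spearman rank
correlation between methylation and %BMIL is computed (average ranks for
ties) and tested with the t approximation

    t = rho * sqrt((n − 2) / (1 − rho²)),  p = 2 · SF_t(|t|, n − 2).

CpGs with p < `alpha_screen = 0.05` are selected for that arm. No
multiple-testing correction is applied by default — the screen is a
deliberately liberal filter ahead of an explicit model-selection stage —
but Benjamini–Hochberg adjustment is available (`bh_correct=True`). An
exact permutation p-value is available for n ≤ 9 (`method="exact"`).
Each arm must contain at least 4 individuals; a probe constant within an
arm gets rho = NaN, p = 1, a warning, and is never selected.

### 3. Certified best-subset selection

For each arm, the selected CpGs (ascending screening p-value, truncated
at `max_candidates = 18`) enter a Furnival–Wilson leaps-and-bounds
search: a branch-and-bound over all 2^p − 1 subsets that returns the
**provably** RSS-optimal subset of every size without enumerating all of
them. The intercept is handled by centering; subset RSS values come from
Cholesky solves on sub-blocks of the precomputed Gram matrix; pruning
uses the monotonicity of RSS in the predictor set. The search is exact —
the test suite verifies identity with exhaustive enumeration — and fast
(p = 18 costs well under a second).

`max_candidates` exists because a liberal screen over a large null probe
pool can pass dozens of CpGs by chance, and exact search cost grows
exponentially; 18 keeps the worst case bounded while exceeding the
subset sizes the criterion ever chooses at cohort scale. It is a design
choice of this package, not part of the published method.

The model size is then chosen by an information criterion
(`criterion = "AIC"` by default):

    AIC  = n·ln(RSS/n) + 2(k + 1)
    BIC  = n·ln(RSS/n) + ln(n)·(k + 1)
    AICc = AIC + 2(k+1)(k+2)/(n − k − 2)
    adjR2 maximized

AIC is the default because the provenance method's criterion is
unstated and AIC is the conventional default of best-subset tooling;
ties break toward the smaller model. A caution: best-subset search
maximizes the spurious-fit advantage of noise predictors, so even BIC
overselects by one variable in a noticeable fraction of replicates
(measured ~20% at n = 200 with 3 strong true predictors among 10); the
chosen subset contains the true support essentially always.

### 4. Refit and prune

The chosen subset is refit by OLS (with intercept). Predictors with
p ≥ `p_keep = 0.19` are dropped in a single pass (the published
criterion retains predictors with p < 0.19), then predictors are removed
one at a time by worst variance-inflation factor while any VIF exceeds
`vif_max = 10`. The literal published phrasing is "VIF > 1", which would
delete any correlated pair whatsoever; 10 is the standard collinearity
threshold and is configurable down to 1 for the literal reading. If
nothing survives, an `EmptyModelError` is raised rather than returning
an empty score.

### 5. Scores

The final coefficients are the per-CpG weights. For individual *i*:

    sub_diet(i) = Σ_j  w_j · m_ij        (no intercept)
    total(i)    = sub_MHP(i) − sub_LF(i)

Missing weighted probes raise `MissingProbeError` by default;
`missing="impute"` substitutes supplied cohort means with a warning.

### 6. Interaction model

    %BMIL ~ const + diet + score + diet:score + age + sex

fit by OLS (`DietResponseModel.fit()`). With one observation per
participant, the mixed-effects formulation with a participant random
intercept is exactly equivalent to OLS: the REML likelihood is flat in
the split between intercept variance and residual variance, and the
fixed effects equal OLS everywhere on that ridge. `fit(method="mixed")`
verifies the flatness numerically and reports the boundary value 0 for
the random-intercept variance; the coefficient table is identical to
OLS.

Marginal predictions at score *t* hold age at its sample mean and sex at
its sample proportion; the standard error at a design row *x* is
`sqrt(x' Cov x)`. Grids extending beyond `extrapolation_factor = 2`
times the observed score range trigger a warning.

### 7. Decision rule

For each individual, %BMIL is predicted under both diets at their total
score and compared with a Z-test. Two variance modes:

- `independent` (default): `var = se_MHP² + se_LF²`. The two predictions
  share every non-diet coefficient and are positively correlated, so
  this is conservative (under-decides).
- `full`: exact variance of the difference,
  `(x_MHP − x_LF)' Cov (x_MHP − x_LF)`. This is the calibrated choice:
  on null cohorts with weights trained on an independent split it
  assigns a diet to ≈ 5% of individuals at α = 0.05 (verified in the
  acceptance suite). Note the calibration requires the interaction model
  itself to be fit on data independent of the weight training; reusing
  the training split leaves the selection circularity in the fit and is
  far from size-α.

p ≤ `alpha_decision = 0.05` recommends the diet with the more negative
prediction; otherwise the category is `either`. A population summary
reports category counts and the score interval(s) occupied by
consecutive undecided individuals.

## Synthetic cohort generator

Scope: the generator exists to validate the pipeline's statistical
machinery, not to be biologically realistic.

- `n_individuals = 201` split `frac_mhp = 93/201` into MHP/LF,
  mirroring the reference cohort's arm sizes.
- High-variance probes (`n_high_var`) draw from Beta(2, 2)
  (population SD ≈ 0.224, reliably above the 0.1 filter); the remainder
  draw from Beta(1, 40) or its mirror (concentrated near 0 or 1,
  reliably below it).
- Disjoint arm-specific effect CpG sets (`n_effect_mhp`,
  `n_effect_lf`) are drawn from the high-variance pool. Slopes are
  ±Uniform(3.4, 9.9) — the magnitude range of the published weights —
  with random sign.
- Outcome: `%BMIL = intercept (−10) + Σ slope·m + N(0, noise_sd = 2.5)`,
  computed from the **observed** (noise-added, clipped) methylation so
  the recorded ground truth reproduces the outcome exactly as noise → 0.
- Per-probe measurement noise `beta_noise_sd = 0.01`, then clipping to
  [0, 1] (`clip_beta=False` disables clipping).
- Age ~ Uniform(18, 67); sex balanced Bernoulli. Neither influences the
  simulated outcome, so covariate adjustment is testable under the null.
- All randomness flows from one `numpy.random.default_rng(seed)`;
  `obekit_like_config()` provides the reference-scale preset
  (201 individuals, 5000-probe desk-scale pool, 1233 high-variance,
  15/11 effect CpGs).

Limitations: no probe-probe correlation structure (no CpG islands or
co-methylated blocks), no cell-type composition effects, no batch
effects, linear outcome model only, covariates truly null. Effect sizes
apply to raw beta values, not M-values.

## Numerical choices

- Spearman rho is computed in-package (vectorized over probes; ranks via
  `scipy.stats.rankdata`) and cross-checked against
  `scipy.stats.spearmanr` in the tests; OLS refits, p-values and VIF go
  through statsmodels; the branch-and-bound search is authored here
  because no installed package offers certified best-subset selection.
- Best-subset RSS uses Cholesky factorization of Gram sub-matrices; a
  numerically singular candidate subset is warned about and treated as
  RSS = ∞ rather than crashing the search.
- p-values are clipped to `(tiny, 1]` to avoid exact zeros.
- Text artifacts write floats with `%.17g` (methylation, phenotypes,
  scores, recommendations) and readers parse with correctly rounded
  conversion, so file round-trips are bit-exact and pipeline runs are
  byte-identical across repeats: no timestamps enter any output, and the
  run fingerprint (`config_hash`) covers all scientific parameters while
  excluding the output directory.
- The bundled two-decimal published weight tables are **truncated**, not
  rounded, from the full-precision tables (e.g. 6.259 → 6.25,
  −8.048 → −8.04); both precisions ship and the fixtures transcribe the
  printed values exactly. The published interaction-coefficient fixture
  stores the age standard error as null because it is printed only as
  "< 0.001".

## Problem sizes exercised

- Unit tests: n = 5–200, p ≤ 12 with exhaustive oracles.
- Acceptance: 50 random best-subset instances vs enumeration; 500
  parameter-recovery replicates at n = 201; 200 null calibration
  replicates (split-sample protocol); two full reference-scale pipeline
  runs (201 × 5000) byte-compared. The whole suite runs in a few
  minutes on one CPU.
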