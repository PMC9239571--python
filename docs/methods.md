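# Methods

## The fusion model

The package analyses two survey files with a block-missing structure:
file A observes an outcome *Y* and shared demographics *X*; file B
observes *X* and an exposure *Z*.  The joint (Y, Z) distribution is not
identified — any partial correlation ρ_{Y,Z|X} is consistent with the
observed margins — so the method treats ρ as an *assumption*, not an
estimate, and proceeds in five stages:

1. the files are stacked, with per-record weights adjusted so each file
   carries a fixed share of the total (default "equal-share":
   weight (n_A + n_B)/(2 n_F) for every record of file F, giving each
   survey half the total weight; "proportional" leaves weights at 1);
2. conditional models Y|X and Z|X are fitted by weighted least squares
   within the file where each variable is observed, with residual scale
   taken as the weighted root-mean-square residual;
3. under the assumed ρ, every record gets a prediction of its missing
   variable from the conditional-Gaussian mean given (X, observed
   variable): Ẑ = x′β̂_Z + ρ (σ̂_Z/σ̂_Y)(y − x′β̂_Y) on A rows.  On B
   rows, where Z is observed, the prediction is the marginal mean
   x′β̂_Z — it exists only as the matching coordinate, which keeps
   "match to the closest predicted value" well defined without
   circularity;
4. each recipient is matched to the donor with the nearest predicted
   value (1-D absolute distance, donors reusable, ties to the lowest
   donor row index) and receives the donor's *observed* value — a hot
   deck, so every imputed value is a realised data value;
5. ρ is varied over a 5-value grid and the per-grid regression
   coefficients are pooled with the multiple-imputation combining
   rules: Q̄ the mean coefficient, W̄ the mean squared standard error,
   B the between-grid variance, T = W̄ + (1 + 1/m)B, and Rubin's (1987)
   small-sample degrees of freedom
   (m − 1)(1 + W̄/((1 + 1/m)B))².  When the grid is degenerate (B = 0)
   the reference distribution reduces to the normal.  A
   `df_method="normal"` switch forces normal quantiles, since the
   pooling convention used for the published analysis is not stated.

### Assumptions and known behaviour

- The prediction step is exactly correct when (Y, Z) given X is
  bivariate Gaussian with linear conditional means — the generator's
  `measurement="gaussian"` mode constructs precisely this case, which
  is why it anchors the recovery experiments.
- Both files must be (approximately) simple random samples of the same
  population.  `SplitSpec.composition_drift` deliberately violates this
  (logistic assignment by demographics) to study the realistic setting
  where the two surveys differ in composition, e.g. a donor survey
  with a ~90% Global-South share against ~31% in the outcome file.
- The matching step requires the conditional models to have genuine
  predictive power.  If X carries no information about Z, the donor
  coordinates x′β̂_Z collapse to near-constant overfitting noise,
  extreme recipients all match a handful of donors, and the fused
  association is an artefact of those few records.  This is a property
  of the method, not of the implementation; with the default generator
  (R² ≈ 9% per conditional model) matching is well behaved.
- The hot deck adds donor residual noise with full variance σ̂_Z²
  rather than the conditional variance σ̂_Z²(1 − ρ²), which attenuates
  the recipient-side regression slope by roughly 1/(1 + ρ²) and the
  pooled estimate by about ρ²/2 (≈ 3–4% at ρ = 0.26).  The recovery
  simulations measure exactly this: mean absolute relative bias ~6% at
  n = 5,000 per file with a correctly specified anchor.
- An optional stochastic mode adds a residual draw of scale
  σ̂_Z √(1 − ρ²) before matching (stochastic regression imputation);
  the default is the deterministic mean, which showed smaller bias.

### The ρ grid and the anchor

The anchor is estimated inside the donor survey as the partial
correlation between each exposure and the donor measure judged the
closest proxy to each outcome, adjusting for the jointly observed
demographics with listwise deletion.  "±5% and ±10%" is read as
*relative* (multiplicative) perturbation of the anchor — percentages
of an estimate; an `absolute` mode (percentage-point shifts) is kept
because the wording is ambiguous.  Grid values are clamped into
(−0.999, 0.999) and sorted with the anchor central.

Two adjustment sets are named in `surveyfuse.design`: the regression
set (income adequacy, education, relationship status, urbanicity,
minority status, health insurance, region) and the anchor set (age
band, relationship status, minority status, income adequacy, health
coverage, HIV status, region) — the published descriptions of the two
differ, and which produced the published anchors is unclear, so both
are explicit constants.  The anchor set substitutes region for country
of residence and has no sexual-orientation or gender-identity
variables, which the generator does not model.

### Covariate sensitivity

The sensitivity variant limits the covariates *of the outcome
regressions* to the reduced set (full minus urbanicity and region)
while the fusion itself keeps conditioning on the full set, mirroring
the analysis plan's wording.  This matters: if the fusion were re-run
on the reduced set, the hot deck would reconstruct
corr(Y, Z | X_reduced) ≈ ρ and erase any omitted-variable signal, so
confounding by a dropped covariate would be undetectable by
construction.  With the regressions-only reading, a covariate that
loads on both Y and Z shifts the reduced-model estimate in the
direction given by the product of its two loadings, as the
confounding test verifies.

## The synthetic generator

A Gaussian copula over 20 latent traits: 9 demographic propensities
(mutually independent by default), 4 exposure traits and 7 outcome
traits.  Structural construction: exposure trait
T_j = a_j′D + λ_j e_j with independent residuals e_j, outcome trait
O_k = b_k′D + Σ_j c_kj e_j + s_k f_k, with c_kj solved so the partial
correlation of (O_k, T_j) given the demographic latents equals the
configured anchor (defaults: the published proxy-anchor table, e.g.
comfort ↔ provider access 0.26, engagement ↔ provider access 0.11).
Demographic loadings default to 0.1 per trait-demographic pair (per
conditional model R² ≈ 0.09 — modest, as demographics typically
predict attitudes weakly); both loading matrices accept per-entry
overrides, which the confounding tests use.  An explicit latent
correlation matrix may be supplied instead; it is validated positive
semi-definite, with the offending eigenvalue reported otherwise.

Realisation modes:

- **gaussian** — all variables continuous latents; the method's exactly
  well-specified case.  Ground truth (regression coefficient and
  partial correlation given the regression covariate set) is
  closed-form from the latent correlation matrix and recorded in a
  `TruthRecord`.
- **likert** (default) — demographics thresholded at the reference
  prevalences of the combined study sample (N = 19,643); exposure
  items generated as one common trait plus independent item noise and
  discretised to 1–5.  Ground truth is then the whole-population fit
  of the realised (discretised) variables, since thresholding
  attenuates the latent values.

Item calibration solves three nested problems per scale: (i) the
discrete inter-item correlation implied by the target Cronbach alpha
for k exchangeable items, r_d = α/(k − α(k−1)); (ii) the item marginal
(a discretised normal on 1..5) matching the reported scale mean and the
item variance k·SD²/(1 + (k−1) r_d); (iii) the latent common-trait
share w such that items thresholded at those cut points have discrete
correlation r_d, found by root-finding on the thresholded
bivariate-normal correlation.  At n = 50,000 the realised scale means
are within ±0.01 and alphas within ±0.01 of the targets (reported
values: engagement 1.32/α .72, comfort 2.98/α .85, stigma 3.53/α .82,
discrimination 1.14/α .87).

Outcome marginals are discretised normals calibrated to the reported
means/SDs on each outcome's support (access items 1–5, provider access
1–4, ART refills 1–2, income reduction 0–10 in 10-point bands, PHQ-4
as four 0–3 items with inter-item correlation 0.45 and total mean 4.7).
Targets incompatible with a support's feasible moment region — notably
ART refills, whose reported mean 2.1/SD 1.2 cannot arise from any
2-point coding — are fitted by bounded least squares and land on the
boundary; all outcome marginals are configuration defaults, not
validated quantities, because the published numeric codings are not
printed.  In likert mode the two outcomes asked only of respondents
living with HIV (provider access, ART refills) are missing for
HIV-negative records.  Each outcome construct also has a continuous
proxy measurement (reliability 1.0 by default, configurable) retained
in the donor file, standing in for the donor survey's own measures of
the outcome constructs used in anchor estimation.

The population splits into the two files by Bernoulli (or exact-size)
assignment, optionally with logistic composition drift;
`drift_for_target_shares` inverts the one-binary-demographic case in
closed form (used to reproduce the 90%/31% Global-South contrast).
Masked variables are removed from the emitted file, not blanked, so
leakage into fusion is structurally impossible.

What the generator does **not** model: country-level clustering,
recruitment-network dependence, survey-mode effects, item-level
missingness beyond the not-applicable rule, sexual orientation and
gender identity, or any non-Gaussian dependence.  Passing recovery
tests therefore show the pipeline is correct *under its own
assumptions*, not that the published coefficients are reproducible —
the original microdata are not deposited, and the published Tables'
values are out of reach by design.

## Numerical choices

- Matching is a sorted 1-D search exactly equivalent to the brute-force
  distance-matrix argmin (first-occurrence tie rule); property tests
  verify equivalence on duplicate-heavy instances.
- Weighted least squares via scaled `lstsq` (conditional models) and
  statsmodels WLS (outcome regressions, classical variance; HC1 robust
  switch off by default).  Rank deficiency is detected and reported
  with the collinear columns from a pivoted QR.
- Partial correlation residualises through `lstsq` and matches the
  recursive closed form to 1e-10 for a single covariate; residuals that
  are numerically constant raise rather than return a value.
- Per-stage seeds derive from the master seed by SHA-256 of
  `"{seed}:{stage}"` reduced mod 2³¹−1, so adding a stage never
  perturbs another stage's stream; identical config + seed reproduces
  byte-identical fixtures and artifact checksums.

## Problem sizes

Default experiment sizes, chosen to keep each simulation comfortably
within a single-CPU interactive run while leaving Monte-Carlo error
well below the quantities measured: calibration checks at n = 50,000;
anchor checks at n = 100,000 (gaussian); effect recovery at 5,000 per
file × 50 replications; null coverage at 2,000 per file × 100
replications; the study-sized fixture at the reference N = 19,643.

## Reference-table notes

The reference demographic counts carry the source tabulation's internal
quirks unchanged: category counts may not sum to the column totals
(item non-response, e.g. Region and Age), and the source text's
"44.00% under 30" is inconsistent with its own counts
((1287 + 7234)/19,643 = 43.38%).  Percentages computed by this package
always come from the counts.
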