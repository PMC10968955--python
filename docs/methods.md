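# Methods

## The exposome score

Ten binary exposure components are scored: winter season of birth
(December–February), obstetric complications (caesarean section for
perinatal complications, birth weight < 2500 g, or preterm birth), advanced
paternal age (father ≥ 35 years at the respondent's birth), non-right-
handedness (left and mixed pooled), four childhood-trauma screens
(emotional neglect, emotional abuse, bullying, sexual abuse), problematic
cannabis use (any of eleven problem items affirmed) and urban upbringing
(any non-rural residence).  Each present component contributes the natural
log of its meta-analytic odds ratio; the packaged weight table stores the
odds ratios together with their published two-decimal log-odds and the
loader refuses to run if `ln(OR)` stops rounding to the published value
(weight fidelity).

Decisions taken where the scoring rules left room:

* **Denominator.** The default policy divides by the fixed component count
  of 10.  Under the default exposure prevalences this makes the analytic
  mean `Σ p_k·w_k / 10 = 0.245`, consistent with the ES mean of 0.25
  reported for cohorts of this type, which is why it is the default.  A
  `per_respondent_recorded` policy (divide by the number of non-missing
  components; undefined when all ten are missing) is available.
* **Obstetric "I don't know".** Any "yes" dominates and marks the exposure
  present; otherwise any "don't know" leaves it missing.  Affirmative
  information is never discarded, and pure uncertainty is never coerced to
  absence.
* **Paternal-age tiers.** Two mutually exclusive tier weights, ln 1.28 for
  35–54 years and ln 2.22 for ≥ 55 years; a respondent contributes exactly
  one of them.
* **Trauma weighting.** The four trauma screens are scored as four separate
  weighted components (distinct odds ratios), not as one pooled exposure.
* Missing components contribute 0 to the numerator under either policy, so
  the ES of a respondent with partially missing exposures is a lower bound
  on the fully observed score.  Scores are reported at 3 decimals;
  internal arithmetic is full precision.

## Synthetic cohorts

`generate_cohort` emulates a web-survey sample of 1100 young adults
(18–35): exposure prevalences between 6.5% (cannabis problems) and 61.1%
(urban upbringing), symptom sum-scores with means/SDs typical of a
non-clinical sample (e.g. PHQ-9 9.4 ± 6.2 on 0–27), and missingness of
21.5% for obstetric answers and 18.2% for paternal age.

* Months of birth are uniform within winter and non-winter, re-weighted so
  winter prevalence hits its target.  Obstetric and cannabis items are
  independent Bernoulli draws with item probability solving
  `1-(1-q)^m = p`, so the any-item rule reproduces the component
  prevalence.  Non-right-handedness splits 2:1 between left and mixed.
* Paternal age is truncated normal (sd 6, range 16–70) with the location
  solved numerically so that P(age ≥ 35) equals the requested prevalence
  (a fixed location of 30 would undershoot it by ~4 percentage points and
  violate the generator's own ±0.01 calibration contract); both tiers
  occur because the upper range extends past 55.
* Symptom scores and age draw a latent normal, round to integers and clip
  to the instrument range.  Clipping pulls means inward — by ≈ 0.43 points
  for OCI-R at the default floor — so the latent location is solved so the
  clipped expectation equals the target; rounding is mean-neutral to first
  order.  SDs are not corrected (no calibration contract on them; the
  realized SD is within a few percent of target).
* Missingness is injected completely at random (MCAR); no mechanism is
  asserted beyond the rates.  Obstetric missingness sets all three items
  to "don't know", matching how the missing count is defined downstream.

What the generator does **not** emulate: item-level questionnaire
structure (only sum-scores), quota/stratified sampling, co-occurrence of
exposures (independent by default — dependence is injected explicitly, see
below), and non-MCAR missingness.  Passing tests on these cohorts
therefore validate the scoring and estimation machinery, not claims about
real survey data.

## Ground-truth MGMs and dependence injection

`sample_mgm` draws from a pairwise Markov random field whose continuous
nodes have linear-Gaussian full conditionals
`N(σ_s²(θ_s + Σ J_st x_t), σ_s²)` and binary (0/1) nodes logistic ones.
Validation requires a symmetric zero-diagonal interaction matrix and a
positive-definite Gaussian block (`K_ss = 1/σ_s²`, `K_st = −J_st`);
otherwise the joint is improper and the error names the first node whose
leading principal minor fails.  Sampling runs n parallel Gibbs chains for
`burn_in + thin` full sweeps and keeps each chain's final state, so rows
are independent draws; the scheme vectorizes across rows.  Defaults
(burn_in 1000, thin 10) are conservative for graphs of ≤ 20 nodes; tests
use shorter chains after verifying agreement with exact enumeration.

`inject_dependence` replaces chosen cohort columns with a joint draw from
a known MGM while preserving marginals: continuous columns are
affine-rescaled to the original sample mean/SD (exact), binary thresholds
are calibrated by damped stochastic approximation on the logit scale
(drift well under two percentage points).  Couplings therefore act on the
standardized scale.  Re-sampled continuous columns are real-valued; they
are not re-rounded to instrument integers, since the injection targets
moments and dependence, not item-level realism.

## Network estimation

Each node is regressed on all others: coordinate-descent lasso for
continuous nodes, liblinear L1 logistic regression for binary nodes
(solver tolerance 1e-7), with continuous variables z-scored and binary
kept 0/1, and the penalty parameterized on the averaged-loss scale.  The
per-node penalty is chosen on a 50-point log-spaced grid from `λ_max`
(full shrinkage, `max |x'(y-ȳ)|/n`) down to `0.01·λ_max` by minimizing

```
EBIC(λ) = −2·loglik + df·ln n + 2γ·df·ln(p−1),   γ = 0.25 by default,
```

with `df` the number of non-zero coefficients and ties resolved toward
the smallest λ.  EBIC with γ = 0.25 is the convention of the
mixed-graphical-model software family this design follows; the penalty
selection rule, γ and the AND/OR choice are recorded in the network
metadata as conventions because analyses of this kind rarely print them.

Edges combine the two directed coefficients as the mean of absolute
values; under the (default, conservative) AND rule an edge requires both
coefficients non-zero, under OR one suffices.  Signs are kept separately:
the common sign when the two coefficients agree, undefined when they
conflict.  Gaussian and logistic coefficients live on slightly different
scales; mixing them in one magnitude is inherited from standard MGM
practice.

Predictability refits the selected neighbourhood without penalty:
R² for continuous nodes; for binary nodes normalized accuracy
`(accuracy − majority rate)/(1 − majority rate)` floored at 0, an
interpretable "variance explained" analogue for classification.  Nodes
with empty neighbourhoods score 0; zero-variance nodes are undefined
(NaN) and excluded from the network mean.

Missing data are handled by listwise deletion over the network variables
(with a logged count) before estimation; exposome scoring tolerates
missing components, so a respondent can be scored yet excluded from the
network.  Education is binarized as higher vs other, gender as male vs
female, employment as employed (part- or full-time) vs not (students and
unemployed) — the employment collapse is this package's choice since
analyses of this kind state only "employed vs unemployed".

## Centrality and stability

Strength centrality is the sum of absolute incident edge weights (defined
with absolute values for generality even though typical networks here
have no negative edges).  Network density is reported as a percentage
rounded half-up to one decimal.

The non-parametric bootstrap resamples rows with replacement and fully
re-estimates the network B = 1000 times (tests and the acceptance script
use B = 100–200 at desk scale); iterations whose resample leaves a column
constant are skipped and logged, never imputed.  The case-drop bootstrap
removes growing fractions of respondents (default grid 0.05–0.75 in 0.05
steps), correlates subsample strength vectors with the full-sample one,
and summarizes stability as the CS coefficient: the largest drop fraction
at which the correlation stays ≥ 0.7 in ≥ 95% of iterations (0 when none
qualifies; constant strength vectors are flagged and excluded from the
quantiles).  Reports flag whether CS-C exceeds the conventional 0.25
acceptability cutoff.  Difference tests use two-sided percentile
intervals of the per-iteration difference (BCa is not implemented;
percentile matches the common practice of the bootstrap-network toolchain
and is recorded as a convention), with a precision warning below 100
retained iterations.  Iteration seeds derive from the run seed through a
counter-based spawn scheme, so results are independent of execution order.

## Numerical choices and problem sizes

* Lasso paths for continuous nodes are computed with warm-started
  coordinate descent over the whole grid in one call; logistic paths fit
  per grid point (p is small throughout).
* Orthonormal-design closed forms (soft-thresholding), OLS via the normal
  equations, exact 4-state enumeration for 2-node binary models, and the
  bivariate-normal correlation identity (unit conditional variances give
  marginal correlation equal to the coupling) serve as independent oracles
  in the tests.
* Recovery exercises use the canonical 11-node graph (6 continuous, 5
  binary, 10 edges of magnitude 0.25–0.45, each ≥ ~5 standard errors at
  n = 2000) over 20 seeds; null calibration uses independent data at
  n = 1100, p = 11 over 50 seeds.  Cohort-calibration checks run at
  n = 50,000–100,000 where Monte-Carlo error is below the contract
  tolerances.  Bootstrap simulations use 4–5-node continuous networks at
  n = 2000 with a 20-point λ grid, sizes at which the bootstrap
  distributions are well resolved.

## Known limitations

* Only binary and Gaussian nodes; no categorical (> 2 level), Poisson,
  moderated or time-varying models.
* Binary-node predictability is normalized accuracy, not a pseudo-R²;
  the two notions differ and neither is canonical.
* The per-respondent denominator policy and the ≥ 55 paternal tier are
  implemented but not exercised by the default pipeline; which variant a
  given published analysis used is generally not stated, so neither is
  asserted as "the" published rule.
* `inject_dependence` matches first moments; higher-order marginal shape
  of replaced continuous columns follows the MGM, not the original
  instrument distribution.
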