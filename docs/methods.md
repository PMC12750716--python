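# Methods

## Scientific setting

`gmediate` estimates how much of the effect of a binary exposure X (a
mother's perception that clinic nurses are helpful "always") on a binary
outcome Y (exclusive breastfeeding in the first days postpartum) runs
through a mediator M (breastfeeding self-efficacy, BSES-SF score), in a
cross-sectional postpartum cohort with measured confounders C (maternal
age, infant age, parity, delivery mode, education, employment, HIV status,
household assets, and two health-literacy indicators).

The estimands are the counterfactual contrasts, on the risk-difference
scale:

- TCE = E[Y(1, M(1))] − E[Y(0, M(0))] — total causal effect;
- NDE = E[Y(1, M(0))] − E[Y(0, M(0))] — natural direct effect, with the
  mediator held at its unexposed level;
- NIE = TCE − NDE — natural indirect (mediated) effect;
- proportion mediated = NIE / TCE.

Identification assumes the usual sequential ignorability given C: no
unmeasured exposure–outcome, exposure–mediator or mediator–outcome
confounding, and no mediator–outcome confounder affected by the exposure.
The package does not test these assumptions; it makes the adjustment
choice explicit through the user-supplied causal diagram.

## G-computation estimator

Two regression equations are fitted on the analysis table:

- M-equation: linear (OLS) regression of the mediator on X and the
  mediator-equation adjustment set. By default M is the raw 14–70 score;
  a dichotomised mediator is supported, fitted either as a linear
  probability model (default, keeping the equation linear) or as a logit.
- Y-equation: logistic regression of the outcome on X, M and the
  outcome-equation adjustment set, fitted by IRLS to the maximum-likelihood
  solution (convergence when the score's max absolute entry falls below
  1e-8, at most 100 iterations). Non-convergence — including perfect
  separation, detected as a numerically zero deviance — is always surfaced,
  never silently accepted.

Counterfactual means are computed by standardization over the observed
confounder distribution. For each record, `mc_draws` (default 100) mediator
values are simulated from the fitted M-equation with the exposure forced to
0 or 1 (gaussian noise at the fitted residual SD for a continuous mediator;
Bernoulli draws for a binary one, with linear-probability predictions
clipped into (0, 1) and the clip count reported). The outcome expectation
at each (exposure setting, mediator draw, confounders) triple is taken
*analytically* from the logistic Y-equation and averaged; this has the same
expectation as drawing Bernoulli outcomes but strictly smaller Monte Carlo
variance. A `draw_y` mode that samples the outcomes exists as a fidelity
check and is tested to agree with the analytic mode within Monte Carlo
error.

Two deliberate numerical choices make results well-behaved:

- The same M(0) draws enter E[Y(0, M(0))] and E[Y(1, M(0))] (common random
  numbers), so NIE = TCE − NDE holds bit-exactly for every run and the
  NDE/NIE split is not inflated by independent simulation noise.
- Each run uses one seeded generator; bootstrap replicate seeds are derived
  from the master seed by counter, so a failed replicate does not shift any
  other replicate's stream and results are reproducible bit-for-bit.

The proportion mediated is reported as undefined (`None`/`null`) when
|TCE| < 1e-10 rather than propagating a division by ~0.

## Adjustment-set selection

The adjustment sets come from a user-supplied DAG (plain-text edge list
with `exposure:`/`mediator:`/`outcome:`/`latent:` role lines).
d-separation is decided by the moralized-ancestral-graph construction.
A candidate set is sufficient for X → Y when it d-separates X from Y in
the graph with X's outgoing edges removed (the backdoor criterion;
descendants of X and latent nodes are never candidates). All minimal
sufficient sets are found by exhaustive subset search in order of
increasing size with superset pruning — graphs in this setting have at
most a dozen-odd nodes, so correctness is preferred over asymptotic
cleverness. The mediator equation's set is computed identically with M as
the temporary outcome. When several minimal sets exist the pipeline picks
the smallest, breaking ties lexicographically, and logs the choice.

The repository ships a *reconstructed* study-style DAG
(`examples/study_reconstructed.dag`); the published diagram is not
machine-readable, so its confounder edges are a plausible reconstruction,
clearly labelled as such, and any user DAG can be substituted.

## Bootstrap inference

Nonparametric bootstrap with the participant record as the resampling
unit: B (default 1000) resamples of n records with replacement, the entire
pipeline (refit of both equations, fresh mediator simulation) rerun per
resample. Per estimand the summary reports the point estimate, bootstrap
SE (sample SD of replicates), z = estimate/SE with a two-sided normal
p-value, the normal interval (point ± 1.96·SE), and Efron's bias-corrected
(BC) percentile interval with

    z0 = Φ⁻¹((#{θ* < θ̂} + ½·#{θ*​ = θ̂})/B),

bounds at the empirical Φ(2·z0 ± 1.96) quantiles by the nearest-rank rule.
BC, not BCa: no acceleration constant is estimated. When the point
estimate falls outside the replicate cloud the bias fraction is clamped to
[½/B, 1 − ½/B] and flagged. Replicates whose models fail to converge are
dropped and counted; the run aborts if more than 5% fail, since silently
discarding many replicates biases the intervals.

## Synthetic cohorts and ground truth

No participant-level data are distributed, so the generator in
`gmediate.simulate` stands in for the study sample. Confounder marginals
are calibrated to the study population: age ~ N(29, 6²) truncated to
18–43; infant age geometric with median 4 days; parity on 1–5 with 66%
having two or more children, positively correlated with age through a
shared latent factor; caesarean 29%; completed grade 12 64%; employed 25%;
HIV 20%; assets ~ Binomial(13, 8/13) (mean 8, SD ≈ 1.8); health-literacy
"high" indicators at 76% and 70%. Confounders are otherwise independent —
a simplification, not a claim about the real cohort. The structural
equations are logistic for X and Y and gaussian-with-rounding-and-clipping
for the 14–70 mediator score; intercepts were calibrated once, numerically,
so that large-sample prevalences hit the cohort's figures (exposure 43%,
outcome 78%).

Two ready-made configurations:

- `study_config()` reproduces the cohort's marginal structure including
  the severe ceiling of the self-efficacy score (55% at 70/70, 14% below
  56, mean 64.9, SD 8.0). Under a ceiling this heavy the linear M-equation
  is intentionally misspecified — exactly the stress the real analysis
  faces. Its true effects are TCE ≈ 0.13 with a near-null mediated path
  (NIE ≈ 0.002), mirroring the study's finding of a direct effect without
  mediation.
- `recovery_config()` (the default validation process) keeps the same
  confounder and exposure structure but centres the mediator near 51 with
  SD ≈ 6.5, so boundary clipping is negligible (<0.3%) and the fitted
  equations are correctly specified. True effects: TCE ≈ 0.136,
  NDE ≈ 0.098, NIE ≈ 0.039 (≈28% mediated). This is the process on which
  estimator bias, null behaviour and interval coverage are measured —
  against a correctly specified model, so that any failure indicts the
  estimator, not the model.

Ground truth is computed by `true_effects`: direct simulation of M(0) and
M(1) from the *true* structural equations (shared noise) on a large
confounder draw (default 10⁶ records), with the outcome expectation taken
analytically; the oracle shares no code path with the estimator. The
committed fixture `tests/fixtures/recovery_truth.json` freezes the truth at
a 4·10⁶-record draw with its generating seed.

What passing tests on these cohorts do **not** show: robustness to
unmeasured confounding, to informative missingness (the generator's
missingness is MCAR by construction), to dependent confounders beyond the
age–parity link, or to mediator measurement error. They validate the
estimation machinery, not the study's identification assumptions.

## Validation problem sizes

The heavy validation suites run at sizes chosen so each check measures
what it claims: parameter recovery uses 200 cohorts of n = 2000 (Monte
Carlo SE of the mean ≈ 0.0014 for TCE, small enough to see estimator bias
at the 0.003 level); interval coverage uses 500 cohorts of n = 500 with
B = 200 (SE of a 95% coverage estimate ≈ 1%); the null-exposure check uses
n = 40 000 per cohort because the median |TCE| bound of 0.005 demands
sampling noise well below it (sd(TCÊ) ≈ 0.93/√n, so n ≈ 2000 would test
noise, not bias), while the null-mediator check keeps n = 2000 since the
NIE's sampling noise is already far below the bound there. Bootstrap SE
stability is checked at B = 250 versus B = 1000 on a fixed cohort.

## Known limitations

- Single mediator, no exposure-induced mediator–outcome confounding, no
  controlled direct effects, no time-varying g-formula.
- BC (not BCa) intervals; no studentized or jackknife alternatives.
- The linear M-equation is a working model; under the real score's ceiling
  it is an approximation, which is why both the raw-score and dichotomised
  mediator routes are exposed.
- Inference on individual regression coefficients uses Wald statistics
  from the estimated covariance; the mediation effects themselves are
  always bootstrap-inferred.
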