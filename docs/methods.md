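# Methods

This note records the models the package implements, the choices made
where the published analysis left details open, what the synthetic-data
generator does and does not emulate, and the numerical decisions that
matter for reproducing results.

## Choice-task models

The four tasks share a two-option structure (option A: immediate /
certain / reject; option B: delayed / probabilistic / accept) and a
logistic choice rule on the subjective value difference,
P(B) = 1/(1 + e^(−β·ΔV)), with one inverse temperature β per task.
Valuation follows the three standard equations (hyperbolic delay
discounting, hyperbolic probability discounting on the odds against
receipt, and linear loss-averse utility for 50–50 mixed gambles).
Loss-task options are valued as signed quantities and the decision-maker
maximizes signed value; this is what makes strong probability discounting
of losses behave as risk-seeking (the discounted probabilistic loss has a
smaller magnitude than the certain loss). Gamble acceptance is valued
against a status-quo of zero; the show-up endowment is bookkeeping and
never enters the value equation. Choice consistency is the mean of
mean-centered log β across the four tasks, so it is only defined relative
to a cohort; the package always requires the centering reference
explicitly. The exact softmax parameterization of the original battery
(shared vs per-task β, any magnitude scaling of ΔV) is not published; the
per-task logistic-on-value-difference form used here is an implementation
choice validated by parameter recovery, not by fidelity to the original
instrument. Discounting of delayed losses, utility curvature, probability
weighting and reaction times are out of scope.

## Adaptive estimation

Each task estimates (log k or log λ, log β) on a dense grid with uniform
prior: log k ∈ [−12, 2] for delay (1/days), [−6, 6] for the probability
tasks, log λ ∈ [−3, 3], log β ∈ [−3, 3], all at 0.05 spacing. These ranges
cover the cohort means by well over three SDs. After each response the
posterior is multiplied by the Bernoulli likelihood of the observed choice
at every node and renormalized (the update is exchangeable, so recorded
sessions can be re-estimated offline in any order). Point estimates are
the MAP node, with exact ties broken toward the smallest axis values. The
next offer is placed at the MAP indifference point: the varying attribute
(delay, probability, loss magnitude) is drawn uniformly from its design
set, the larger amount is drawn from the upper half of the 0.30–10 EUR
range on a 0.10 EUR grid (1 EUR grid and 1–40 / 5–20 EUR bounds for
gambles), and the adjustable amount is snapped to the grid and clipped to
the bounds, so degenerate indifference points fall back to the nearest
bound. Before any data the anchor is the prior-grid midpoint. Practice
trials and payout bookkeeping are not simulated; they carry no estimation
role. Session lengths default to 30 trials (40 for gambles).

Recovery under these settings (the committed pilot, reproduced by the
acceptance script): median |log k̂ − log k| ≈ 0.10 over 200 simulated
30-trial delay sessions at cohort-typical parameters, ≈ 0.25–0.30 at 10
trials. The 0.7 tolerance asserted in tests is deliberately loose relative
to the pilot. β is weakly identified within a single session (offers near
indifference are uninformative about it); only the preference parameters
are held to recovery tolerances.

## Synthetic cohort

The generator emulates the published study design: n = 198 men, five
baseline choice dimensions drawn from a multivariate normal with the
published means, SDs and correlation matrix; three repeated outcomes
generated from latent growth curves with the published group-curve
components and standardized covariate effects; monotone dropout that hits
the published retention counts (198, 166, 160, 135, 100, 85, 84) exactly.
AUD criterion counts are measured at years 1, 2, 4, 5, 6 and the two
consumption outcomes at years 0–6; this occasion structure is implied by
the published descriptive table and confirmed by degrees-of-freedom
arithmetic (5- vs 7-occasion models).

Quantities the study did not report are calibrations, not published
values:

- the SD of the consistency score (0.6);
- total latent SDs — typical use (35, 8, 1.3), average use (10, 2.7,
  0.40), AUD criteria (0.55, 0.08) — and latent correlations
  ((I,L) = −0.35, (I,Q) = 0.15, (L,Q) = −0.85; −0.3 for the 2-factor AUD
  model); occasion residual SDs 20, 6 and 0.45. These keep the implied
  occasion-level SDs within a factor of ~2 of the published descriptives.
  The average-use latent SDs were additionally calibrated so that the
  model-implied cumulative-intake contrast at M±1SD of delay discounting
  reproduces the published 28.3 / 24.9 kg pair (the analogous published
  pair for risk aversion for gains cannot be matched simultaneously by any
  choice of SDs consistent with the occasion-level descriptives; the delay
  pair was chosen as the anchor);
- unstandardized covariate effects are back-computed as
  b = β_std · SD(factor)/SD(covariate), so re-standardizing a fitted model
  recovers the generating β_std by construction.

Observation noise is added first, then values are floored at zero
(consumption and counts are non-negative), then AUD counts are rounded.
Dropout is monotone and shared across outcomes; MCAR selects droppers
uniformly among survivors, MAR weights selection by the z-scored previous
occasion of the first outcome through a logistic link with coefficient
0.5. What the generator does **not** emulate: drink-type composition,
item-level interview responses, non-monotone (intermittent) missingness,
heavy-tailed or skewed consumption distributions, and any treatment of the
flooring in the fitted model. Passing recovery tests therefore shows the
estimators work under the stated generative model, not that the published
coefficient values would replicate on real interview data.

## Growth-curve engine

The model is the standard latent growth curve with fixed loadings (1, t,
t²), zero measurement intercepts, free latent means and covariance, free
occasion residual variances, and (in final models) free regressions of
the latent factors on the five mean-centered covariates, whose means and
covariance are also free. Degrees of freedom are k(k+3)/2 sample moments
(k = occasions + covariates) minus the free-parameter count.

FIML sums each participant's multivariate-normal log-density over their
observed subvector. Two implementation points matter for speed and were
validated against brute-force oracles: participants are grouped by
missingness pattern and summarized by per-pattern sufficient statistics
(likelihood evaluations cost O(patterns), independent of n), and because
the joint likelihood factorizes as f(y|x)·f(x), the covariate moments have
closed-form MLEs and the optimizer only handles the conditional
parameters. Optimization is L-BFGS on a transformed parameterization
(Cholesky factor of the latent covariance with log diagonal, log residual
variances) with an analytic gradient, so every iterate is admissible;
convergence is flagged on the result, never raised. Start values come from
per-participant OLS curve fits regressed on the covariates. Standard
errors are the inverse observed information on the natural scale, with the
conditional Hessian computed by central differences of the analytic
gradient. Participants with no observed outcome are dropped when the model
has no covariates and contribute only the covariate block otherwise.

The saturated (unstructured mean/covariance) log-likelihood under
missingness is maximized by EM with the same per-pattern statistics
(relative tolerance 1e−10); the independence baseline for CFI/TLI (free
means and variances, zero covariances — the conventional choice; the
original report does not name its baseline) factorizes per variable and is
closed-form. RMSEA uses the N−1 convention, which reproduces the published
0.065 for (χ² = 70.967, df = 39, N = 198) where N would give 0.064; its
90% CI inverts the noncentral χ² CDF at the 0.05/0.95 tails by bracketed
root-finding. The χ²-difference test compares nested orders (linear in
quadratic, Δdf = 4: quadratic mean, variance and two covariances) and the
selection rule keeps the restricted model iff p ≥ 0.05. Standardized
effects are b·SD(x)/SD(factor) with the factor SD from the model-implied
total latent variance. p-values are reported but drive no decision other
than the stated 0.05 selection rule. General SEM path models, robust
estimators, ordinal-indicator models for the count outcome and
multiple-group models are out of scope.

## Trajectories and cumulative intake

With centered covariates the latent means are the group curve; M±1SD
trajectories shift every factor by ±b·SD(x) for one covariate with the
others at their average, so the two shifted curves mirror around the group
curve exactly. Cumulative intake integrates the g/day polynomial in closed
form over the 6-year follow-up using 365.25-day years, flooring negative
stretches at zero before integration (both conventions are undocumented in
the original report; 365.25 makes the published group curve integrate to
26.55 kg, the midpoint of the published 28.3/24.9 kg M±1SD pair). A
labeling helper flags trajectory values above the WHO heavy-episodic
threshold of 60 g per occasion. Confidence bands on implied trajectories
would require the sampling covariance of nonlinear transforms and are
future work.

## Problem sizes and numerical tolerances

The test suite and acceptance script use the study's own sizes where the
check is about the design (n = 198 pipelines with the published retention;
200 adaptive sessions) and conventional recovery-study sizes elsewhere
(100 replicates at n = 500 for CI coverage; n = 5000 for standardized
effect recovery, where Monte-Carlo noise on a standardized effect is
≈ 0.015). The coverage study disables the floor-at-zero truncation: CI
coverage is a property of the estimator under its own Gaussian model, and
the floor is a deliberate misspecification for realism whose bias
(≈ 1–2.5 g/occasion at mid follow-up for typical use) is comparable to the
n = 500 standard errors. Posterior grids are normalized to 1e−10 after
every update; FIML optimizations use ftol 1e−11 and gtol 1e−8; the EM for
the saturated model stops at relative change 1e−10. Exact posterior ties
break toward the smallest grid values; covariance starts are repaired by
eigenvalue clipping when indefinite.

## Known limitations

- The fitted Gaussian growth model is misspecified for the floored,
  rounded AUD counts; estimates remain interpretable as moments but the χ²
  calibration is approximate for that outcome.
- Session-estimated covariates carry estimation error, attenuating
  covariate effects in the end-to-end pipeline relative to generating
  values (a realistic feature, not a bug; the pipeline can be run with
  true covariates instead).
- With n = 198 the quadratic term of average use is selected only in a
  fraction of seeds under the calibrated effect sizes; the selection rule
  itself, not the selected order, is the tested contract.
- The MAR dropout coefficient (0.5 per SD of the previous outcome) is a
  stress-test setting, not an estimate from the study.
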