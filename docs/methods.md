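# Methods

This note documents the statistical machinery, the choices made where the
method family leaves options open, and what the synthetic-data checks do and
do not establish.

## Setting and estimand

Two induction regimens are compared without a head-to-head trial. One side
("mod", the pooled modified-dosing population) is treated as the aggregate
target; the other ("label") contributes individual patient data (IPD). The
comparison is an *unanchored* MAIC: there is no common comparator arm, so
the analysis assumes that conditional on the matched baseline covariates,
absolute outcomes are exchangeable across trials. That assumption is strong
and untestable from the data; residual confounding by unmatched prognostic
factors (e.g. cytogenetic risk, era of care, response-assessment criteria)
is the dominant threat to validity and is not correctable by weighting.

Orientation: all effects are mod vs label — HR < 1 and OR > 1 favour mod;
rate differences are mod minus label in percentage points.

## Pseudo-IPD reconstruction from published curves

When a comparator trial reports only a Kaplan–Meier figure, per-patient
`(time, event)` pairs are recovered from the digitized curve coordinates and
the number-at-risk table. The solver works interval by interval between
adjacent at-risk times: within an interval it places a trial censor count at
equally spaced quantiles, derives the event count at each digitized drop
from the ratio of the digitized survival to the running product-limit value
(`d = round(n·(1 − S_click/S_run))`), and adjusts the censor count until the
implied number at risk at the interval end equals the published count.
Iteration on an integer count converges in a handful of steps; when integer
rounding leaves a small terminal discrepancy the closest solution is kept,
and small deficits (at most `max(2, 25%)` of the interval's events) are
reconciled by removing trailing events, the at-risk table being treated as
authoritative. Gross contradictions raise an infeasibility error naming the
interval.

Numerical choices:

* **Deterministic censoring placement** (equally spaced quantiles rather
  than sampled): reconstruction of a given curve is exactly reproducible,
  and at the resolution of a digitized figure the placement scheme is not
  identifiable anyway.
* **Calibration to the reported total event count** when available; without
  it the interval solution stands and a warning notes the wider uncertainty
  in the tail.
* **Digitization jitter**: upward survival steps ≤ 0.005 are clamped to
  monotone (plot-extraction noise); larger violations are rejected.
* Patients still at risk after the last digitized time are censored there.

In the no-censoring case with an at-risk entry at every event time the
reconstruction is exact. With ~20% censoring, 40 grid points and at-risk
counts every 6 months, the reconstructed KM deviates from the source by
< 0.02 absolute survival at every grid point (checked in the suite and by
`scripts/acceptance.py`).

## Weight estimation

Match covariates are encoded as one design column per target, centred at the
target value: continuous means as `x − target`, category proportions as
`I(level) − target` (dummy coding: female, non-IgG, ISS III and ECOG 0 are
the reference categories; ISS enters as two columns, I and II), and medians
as `I(x ≤ target) − 0.5`. Indicator matching at the target median is the
device that makes the weighted median equal the target; it is exact up to
ties at the cutpoint.

Weights are the exponential tilt `w_i = exp(z_i' β)` with `β` minimising
`Σ_i exp(z_i' β)` — the method-of-moments MAIC estimator. The objective is
convex; Newton with backtracking line search from `β = 0` reaches gradient
norms below 1e-8 on all feasible fixtures, with a BFGS fallback for
ill-conditioned designs. At the optimum the weighted mean of every centred
column is zero (enforced to 1e-6), i.e. the weighted sample matches the
aggregate profile exactly. Infeasible targets — a target outside the convex
hull of the sample covariates, detectable as a centred column that never
changes sign, or as diverging coefficients — raise a diagnostic error
rather than returning degenerate weights.

Precision loss is summarised by the Kish effective sample size
`ESS = (Σw)²/Σw²`, scale invariant, equal to n only for uniform weights.
Separate weight sets are estimated for the efficacy and the safety analysis
populations, mirroring the two analysis sets of the source design (the two
populations differ slightly on the aggregate side, hence two ESS values).
Missing matched covariates exclude the patient from weighting with a logged
count; no imputation.

## Endpoint comparisons

**Binary endpoints.** Rate difference with Wald CI; odds ratio with Woolf
(log-OR Wald) CI; two-sided Fisher exact p by hypergeometric enumeration in
the minlike convention (sum of table probabilities ≤ the observed table's,
with 1e-7 relative tie tolerance). These CI methods reproduce the published
naive intervals exactly at the printed rounding, which is what identifies
them; conventions differ enough across software that the choice is
documented here. A zero cell leaves the OR undefined; a 0.5
continuity-corrected value is reported separately as a sensitivity figure,
never silently substituted.

In weighted analyses the label-arm proportion is the weighted proportion and
the effective denominator is the ESS; for the exact test the weighted
responder count is rescaled to sum to the ESS and rounded to the nearest
integer. The weights are analytic, not frequency, weights, so some integer
table must be chosen for an exact test; the ESS-rescaled table is the one
whose precision matches the weighted estimator's. With unit weights all
weighted formulas reduce exactly to the unweighted ones.

**Time-to-event endpoints.** A weighted Cox model with the treatment
indicator as the only covariate, case weights in the Breslow partial
likelihood, Newton-maximised; the CI uses a robust sandwich variance built
from per-subject score residuals, because model-based variance treats
weights as frequencies and is anticonservative. Breslow tie handling is
used: reconstructed and simulated data carry few exact ties, and Breslow
keeps the weighted estimator's duplication property (integer weights
reproduce the physically duplicated sample exactly). P-values come from the
weighted log-rank test — weighted observed-minus-expected with weighted
hypergeometric variance — which reduces to the classical log-rank under
unit weights.

**Classification.** With two-sided alpha 0.05: significant results are
superior or inferior by direction of the estimate; non-significant results
are noninferior when the CI excludes a disadvantage beyond the margin
(benefit rate difference: lower bound > −13 pp; harm rate difference: upper
bound < +13 pp; hazard: upper CI bound < margin), otherwise inconclusive.
A p exactly at alpha takes the margin path. The source material assigns the
1.333/1.298 HR margins inconsistently between its methods text and its
figure note; the default follows the figure note (OS 1.333, PFS 1.298) and
`MarginSet` makes both configurable — for the published survival statements
both assignments classify identically. Likewise the ECOG reference category
is stated ambiguously in the source's footnotes; the default models the
ECOG ≥ 1 indicator with ECOG 0 as reference.

## Synthetic data generator

The generator emulates the published baseline structure: age from a
truncated normal (18–80 y), sex/ECOG/myeloma type as Bernoulli, ISS as a
three-level categorical, creatinine clearance log-normal with the stated
median; the two default configurations reproduce the two published baseline
columns (medians 58/57 y, male 58/58%, ECOG ≥ 1 52/56%, IgG 61/66%, ISS I
41/34%, ISS II 43/44%, CrCl medians 95.2/82.5 mL/min) with trial sizes
591 and 130. Responses are ordinal with nesting guaranteed by construction
(one latent uniform per timepoint against strictly ordered logistic
thresholds); survival is Weibull proportional hazards by inverse transform
(OS shape 1.2/scale 180 mo; PFS 1.1/60 mo) with administrative-uniform
censoring windows of (3, 40) vs (6, 72) months to mimic the differing
follow-up of the source trials; safety flags are rare Bernoulli events at
roughly the published naive rates.

A deliberate design choice: outcome models depend on covariates only
through the indicator basis that the default match specification balances
(age ≤ 58, male, ECOG ≥ 1, IgG, ISS I, ISS II, CrCl ≤ 95.2). Because the
covariates are generated independently, an exponential tilt on that basis
preserves independence and transports the full outcome-relevant
distribution — so weighting one default trial to the other's profile makes
the weighted outcome estimates consistent for the target population, and
the end-to-end recovery check (200 replicates, mean bias < 1 pp) is a sharp
test of the whole pipeline rather than a fuzzy one. The corollary is the
generator's main limitation as a model of real data: real covariates are
correlated, real outcome models are not exactly indicator-logistic, and
real cross-trial differences include unmatched prognostic factors. Passing
the recovery check therefore validates the machinery, not the
exchangeability assumption; the optional unmatched-confounder switch
(`confounder_prob`, `confounder_log_or`) exists precisely to demonstrate
the residual bias weighting cannot remove.

Determinism: all sampling uses numpy's PCG64 generator seeded from the
configuration, so tables are bit-reproducible across runs and platforms.

## Problem sizes and tolerances

The simulation-based checks use: 100 replicates of n = 2000/arm exponential
survival (true HR 0.70, ~20% censoring) for the weighted-Cox bias check
(mean estimate within ±0.01); 200 replicates of n = 500 for the MAIC
recovery check; 500 replicates of n = 200 for log-rank type-I error
(nominal 0.05, accepted band 0.03–0.07); n = 300 with a 40-point grid for
the KM round trip; n = 100 000 single draws for law-of-large-numbers and
centring checks (tolerance 0.02). Moment constraints are enforced to 1e-6,
optimiser gradients to 1e-8, closed-form identities checked to 1e-6 or
better.

## Known limitations

* Unanchored MAIC identifies the estimand only under conditional
  exchangeability over the matched covariates; no diagnostic in this
  package can verify that assumption.
* Weight-estimation uncertainty is not propagated into CIs (weights are
  treated as fixed, as in the source analysis); ESS understates this.
* The published weighted results (ESS 105/116, weighted HRs and table rows)
  require the original trials' IPD, which is not publicly deposited; the
  package validates its weighted machinery by exact identities and
  simulations with known truth instead.
* The exact-test convention for weighted counts (ESS-rescaled, rounded) is
  one reasonable choice among several; p-values near thresholds can move
  by small amounts under alternatives.
* The KM reconstruction inherits digitization error and cannot recover
  covariates, only `(time, event)` pairs; reconstructed patients enter
  survival comparisons but not the matching model.
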