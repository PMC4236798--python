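# Methods

## Problem setting

The package derives a bedside-computable risk screener for hospital or
emergency-department (ED) use among home-care clients aged 60+. The input
is one row per person: binary assessment items grouped into nine domains
(clinical complications, disease diagnoses, specialized treatments,
cognition/communication, mood/behavior, social supports, function,
environment, services), a baseline prior hospital/ED-use flag, and a
binary follow-up hospital/ED outcome. Real repositories of this kind are
proprietary, so the package ships a synthetic generator that emulates the
statistical structure the derivation procedure assumes; the pipeline
itself is data-agnostic and reads any cohort CSV in the documented schema.

## Synthetic cohort model

Outcomes are drawn from a planted logistic model

    logit P(y = 1) = alpha_c + sum_j beta_j x_j + beta_prior * prior,

with items x_j independent Bernoulli(prevalence_j) and the prior-use flag
an independent Bernoulli (default prevalence 0.45, consistent with the
high baseline utilization of home-care populations).

Default planted truth (the `default_catalog()` profile, 123 items):

- **16 risk items** with true conditional OR 1.5–2.0, spread over the
  clinical-complication (7), disease (4) and treatment (5) domains. Rare
  complex treatments carry the larger ORs (e.g. IV infusion: OR 2.0 at
  prevalence 0.02) and common items the smaller ones (falls, polypharmacy:
  OR 1.5 at prevalence 0.30–0.35), so each item's *marginal* OR clears the
  1.30 screen with comparable headroom at derivation-scale n.
- **2 protective items**: a dementia (Alzheimer's-type) diagnosis
  (OR 0.60, prevalence 0.12) and day-care participation (OR 0.65,
  prevalence 0.10). Protective effects are planted simply as negative
  log-odds; no separate mechanism. The marginal ORs attenuate toward 1
  under covariate mixing (to roughly 0.63 and 0.68), still clearly below
  the 0.75 screen threshold.
- **105 null items** (beta = 0) with deterministic prevalences between
  0.03 and 0.40.
- **Prior use**: OR 4 by default. This magnitude matches the qualitative
  regime in which baseline utilization is the single strongest predictor
  of follow-up utilization.
- **Six cohorts** with intercepts calibrated (first order: logit(target)
  minus the mean planted linear-predictor load) to a marginal event-rate
  spread of roughly 27–41%. The calibration is deliberately approximate —
  the expit's curvature shifts realized rates up a few points — because
  only the cross-cohort *spread*, not any absolute rate, is part of the
  emulated structure.

Items are independent by default. Real assessment items are correlated;
independence keeps truth recovery analyzable and is sufficient for testing
the pipeline's logic. An optional within-domain block correlation
(`domain_correlation` = rho: shared latent Gaussian per domain, items
thresholded at the normal quantile of their prevalence) is available but
off by default. Consequently, passing tests demonstrate that the
*procedure* recovers a known truth under its own assumptions — they do not
certify performance on correlated real-world items, where univariate
screens admit confounded proxies by design.

Ages are uniform over [60, 100] and carried as metadata only; the model
uses no continuous covariates. One master seed drives generation;
per-stage child seeds are spawned deterministically (SeedSequence), so
every artifact is bit-reproducible.

## Screening

Each item is cross-tabulated against the outcome separately in the
derivation (default 2/3) and validation (1/3) samples. The dual-sample
rule — OR >= 1.30 in *both* samples for risk, <= 0.75 in both for
protective — operationalizes "identify on derivation, confirm on
validation" as a symmetric threshold test; a config switch
(`require_validation_confirmation=False`) reverts to derivation-only.
Thresholds are inclusive: exactly 1.30 is risk, exactly 0.75 protective.

Zero cells receive the Haldane–Anscombe correction (add 0.5 to all four
cells), applied only when at least one cell is zero, so tables with no
empty cells are untouched. A table that is all zeros has no defined OR and
is reported as neutral by the bulk screen (raised as an explicit error in
the single-table API). No confidence intervals are attached: at the sample
sizes this design targets, near-null associations are significant anyway,
which is precisely why the procedure thresholds on effect size.

The poolability check computes whole-cohort ORs for five probe items —
pneumonia, congestive heart failure, urinary tract infection, the
dementia diagnosis, nine-plus medications — and passes iff every probe's
ORs lie on the same side of 1 in all cohorts. This is directional
consistency only; no formal homogeneity test (e.g. Breslow–Day) is
imposed, since the pooling rationale is qualitative. The dementia probe is
coded disease-present and expected below 1. All five default probes carry
planted effects in the default catalog — a probe with a truly null effect
would make directional consistency a coin flip, so the check would be
ill-posed.

## Logistic fit and staged selection

The logistic MLE is computed by Newton-Raphson/IRLS on the full design
(intercept plus 0/1 covariates): convergence when the score vector's
max-norm falls to 1e-8, at most 100 iterations, Newton steps damped to a
max-norm of 10, separation declared when any |beta| exceeds 15. Constant
outcome or covariate raises a degenerate-design error. Warm starts from
the incumbent model make the forward-selection scans cheap. The fitter is
validated in the suite against an independent BFGS maximization of the
likelihood and against statsmodels GLM.

Selection runs in two stages. Stage 1 considers only screened candidates
from the three clinically compelling domains (clinical complications,
diseases, treatments); stage 2 adds the remaining six domains' candidates
to the surviving pool. Within a stage, forward selection enters the
candidate with the largest likelihood-ratio statistic while its chi-square
p-value is below `entry_alpha` = 0.05. The entry rule is a design choice
(the retention rule below is the procedure's defining constraint, and the
selection trace in the model JSON makes the choice auditable; backward or
bidirectional variants were not implemented).

After every entry, the retention rule prunes any covariate whose adjusted
OR is below 1.2 in the derivation model **or** in the same covariate set
*refit* on the validation sample; protective covariates are held to the
reciprocal bound (OR <= 1/1.2) rather than excluded, since their planted
role is to enter the model with OR < 1. Refit-on-validation (coefficients
re-estimated) is the default reading of "meets the threshold in both
samples", because distinct per-covariate derivation and validation ORs are
reported for the final model; evaluating frozen derivation coefficients is
available via `validation_refit=False`. Pruned covariates are barred from
re-entry, which guarantees termination: every loop iteration permanently
consumes at least one candidate. This entry-then-prune cycle is what keeps
null candidates out at scale — a null item can win a marginal entry test,
but its adjusted OR hovers near 1 and fails retention in both samples.

## The index

Final-model covariates with OR > 1 become risk items, OR < 1 protective
items; an OR of exactly 1 is rejected as ambiguous. The score is the
unweighted count of risk items present (no coefficient weighting — the
index's point is transparency), minus one point if *any* protective factor
is present ("one or both": the decrement is idempotent in the number of
carriers), floored at zero (the category axis starts at 0; no negatives),
and capped at 6 ("six or more"). The extended 0–12 variant maps
no-prior-use persons to their 0–6 category and prior-use persons to
7 + min(adjusted, 5): the no-prior block has seven cells but the prior
block only six, so prior-use scores of five and above share the top cell —
the least-surprising resolution of an asymmetric published layout.

The canonical 16-item default definition ships as data
(`default_index_definition()`, serializable to JSON), listing 14 named
final-model items plus two slots filled with nine-plus-medications and
congestive heart failure — both screened risk factors with face validity,
chosen because the published final-model listing names only 14 of its 16
covariates. Home health aide, protective univariately, is deliberately
absent from the default protective pair (dementia diagnosis, day care),
matching the final-model pair rather than the screen. All definitions are
data, not code: alternative slot choices are a JSON edit.

## Evaluation

Stratified rates are exact counts/proportions via groupby; empty strata
report n = 0 with an undefined (NaN) rate. Disease subgroups are simply
item-defined restrictions (records with the item = 1). The monotonicity
report tolerates adjacent-category dips up to 2 pooled binomial standard
errors, because the expected gradient is qualitative and small-cell noise
should not flag violations. Refinement consistency (cohort-refined rates
aggregate back to marginal rates by weighted average) and count
conservation are tested invariants. No discrimination metrics (AUC etc.)
are offered: the index's acceptance surface is the rate gradient, not a
ranking statistic.

**Prior-use crossing.** Whether prior-use/category-0 persons out-use
no-prior/category-6 persons is a *regime* property, not a universal one:
with planted per-item ORs of 1.5–2.0, six accumulated items contribute
more than log(4) to the linear predictor, so the no-prior top category
wins. The crossing emerges exactly when the prior-use effect outweighs the
accumulated per-item load — demonstrated with the `risk_or=1.2`,
prior-OR-4 catalog variant, which mirrors the attenuated per-item effects
real correlated data produce. Both regimes are reported by the analysis
drivers and the acceptance script.

## Problem sizes and numerical choices

Tests and the acceptance script use 50,000 persons per split for
screening/selection recovery, 100,000 for rate-gradient checks, 20,000 for
the exhaustive best-subset cross-check (all C(23,3) subsets), and 8,000
for byte-level pipeline determinism — sizes at which every planted margin
is several standard errors wide while the full suite stays fast.
Recovery checks average over multiple generator seeds; single-seed
fluctuation (e.g. a protective item's marginal OR of ~0.68 against the
0.75 threshold) is expected and is why the acceptance checks are framed
over seed ensembles.

Known limitations: no missing-data handling (complete cases by contract),
no ordinal/ICD emulation, no item correlation by default (see above), no
interaction terms, no regularized alternatives, and intercept calibration
only to first order.
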