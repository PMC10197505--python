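# Methods

This note documents the models and procedural choices behind `dualread`: the
outcome-labelling rules, the decision-fusion workflows, the statistical
machinery, the workload model, and — in most detail — the synthetic-cohort
generator, including what it deliberately does and does not emulate.

## Outcome labelling

Every screening case is assigned exactly one of four categories, in this
order of precedence:

1. **Screen-detected positive** — the historical workflow recalled the case
   *and* a pathology-proven malignancy is dated within the screen-detection
   window (default 180 days) of the screen.
2. **Interval cancer (IC)** — otherwise, a malignancy is proven within one
   screening interval (1,095 days for three-year programmes, 730 for
   two-year ones).
3. **Confirmed negative** — otherwise, a follow-up mammography read exists at
   least 1,035 days after the screen (two months less than a three-year
   interval, tolerating scheduling jitter) with no malignancy proven before
   it.
4. **Unconfirmed** — everything else. Unconfirmed cases remain in the cohort
   and enter the whole-population metrics.

All window arithmetic is in whole days and inclusive of the boundary day
("within 180 days" admits day 180); the boundary convention is fixed once
here and tested explicitly at 180/730/1,035/1,095 days. Precedence of
screen-detected over interval cancer makes the two positive classes a
disjoint union. Two corners the rules must decide:

* a case recalled historically whose *first* malignancy falls after the
  detection window but inside the IC window is an **interval cancer** — the
  recall did not yield a confirmed diagnosis in time;
* a malignancy proven *after* the IC window but *before* an otherwise
  qualifying follow-up read blocks confirmed negativity, leaving the case
  **unconfirmed** ("no proof of malignancy in between" is evaluated up to
  the qualifying read).

Benign pathology neither confers positivity nor blocks negativity.

## Decision fusion

Historical double reading: agreement on "no recall" is final; agreement on
"recall" is final unless the site's policy arbitrates agreed recalls (a
per-site flag, default off); disagreement is resolved by the recorded
arbitration opinion, falling back to the recorded final decision when the
arbitration column is absent (the recorded final embeds the arbitration
outcome). If the recorded final contradicts the replayed decision, the
recorded value wins for historical metrics — it is what actually happened —
and the discrepancy is logged as a data-quality warning.

Double reading with AI keeps the first human reader and substitutes the AI
for the second. Agreement in either direction is final and never arbitrated
(agreed-recall arbitration is a property of the historical workflow only).
On disagreement, the historical arbitration opinion is used when one exists;
otherwise the historical second reader's opinion stands in for the
arbitrator — and since no historical arbitration took place, that opinion
necessarily agrees with the first reader's.

The **arbitration rate** is defined as the disagreement rate between the two
readers of the workflow (first vs second human historically, first human vs
AI in simulation). The per-case trace also carries an `arbitrated` flag that
additionally covers policy arbitrations of agreed recalls, so both counts
are available.

## Metrics and statistical testing

Denominators follow screening practice: recall rate, CDR and arbitration
rate are computed on the whole population including unconfirmed cases;
sensitivity on confirmed positives (screen-detected ∪ interval cancers);
specificity on confirmed negatives; PPV on recalled cases. CDR is reported
per 1,000. Undefined metrics (empty denominator) are flagged rather than
propagated as NaN.

Proportion CIs default to Wilson (well-behaved at CDR-scale proportions of
~0.008), with Clopper–Pearson selectable; both delegate to statsmodels. The
ratio comparison uses the Katz log-method interval for independent
proportions. The within-cohort design is actually paired; a seeded
parametric-bootstrap interval is available as a sensitivity analysis (and is
the automatic fallback when the comparator count is zero, where the Katz
interval is undefined). Katz was chosen as the default because it is the
standard ratio-of-proportions method and the published comparison surface is
driven by point ratios; tests verify its endpoints against an independent
10⁵-replicate bootstrap oracle to <5% relative on count configurations ≥30.

For the non-inferiority bound of lower-is-better metrics the default is
1 + m (1.10) rather than 1/(1 − m) (1.111…); the two differ by under a
percent at m = 0.10 and never change a verdict on the published
comparisons. The reciprocal rule is selectable, and is the one under which
lower-better/higher-better verdicts are exactly mirror images (the
orientation-symmetry property test uses it). Verdicts are monotone:
shrinking the margin or widening the interval can never upgrade a verdict.
No multiplicity adjustment is applied across metrics or strata, matching
the evaluation design this package models.

The workload model prices a case at `base reads + arbitration rate ×
multiplier` with the multiplier in [1, 4] — arbitration reads are reported
to take up to four times a standard read. The algebraic form is this
package's reconstruction of that qualitative statement; it reproduces both
published endpoints (44.8% reduction at multiplier 1, 30.0% at 4, for
arbitration rates 3.3% → 12.3%) exactly.

## Eligibility filtering

The flow removes non-4-view cases, restricts to the selection date range,
then removes *all* cases of an exact-count random sample of participants
(`round(fraction × participants)`, sampled without replacement from the
sorted participant universe with a named, seeded generator recorded in the
exclusion log). Exclusions are logged one row per case in flow order.
Because the participant draw removes an exact fraction of whatever universe
it is given, re-applying a non-zero exclusion to its own output draws a
fresh sample; repeated application is therefore only an identity for the
deterministic filters and a zero fraction. Exclusion is strictly
participant-level: no participant ever has cases on both sides.

## Synthetic cohorts

The generator emulates the structure of a multi-site retrospective screening
cohort; its defaults are the study conditions of the evaluation the package
models.

**Strata and demographics.** Four site/vendor strata with weights
30.2% / 25.0% / 23.4% / 21.3% (MK–IMS Giotto, NUH–GE, LTHT–Hologic,
ULH–Siemens) and the corresponding age-band mix (dominated by 50–69). One
case per participant by default; a repeat-attendance fraction is
configurable.

**Disease classes.** Each case is screen-detectable cancer (0.84%),
interval-type cancer (0.14%; radiologically occult at screening but
surfacing within the interval), or cancer-free. Cancer-free cases receive a
qualifying negative follow-up read with probability 0.30 — a value
consistent with the confirmed-negative pool sizes implied by the published
specificity confidence-interval widths — and are otherwise destined to stay
unconfirmed.

**Opinions.** Conditional on class and stratum, each reader recalls with
probability `sens` (screen-detectable), `ic_hit` (interval-type), or
`1 − spec` (cancer-free). Defaults: first-reader and standalone-AI ten-year
sensitivity/specificity per stratum as published; the second reader is
assumed comparable to the first and the arbitrator slightly more sensitive
(neither is published). `ic_hit` defaults are the published pooled interval
cancer detection fractions (7% human, 30% AI, 15% arbitrator). The published
per-stratum `sens`/`spec` pairs describe performance on *confirmed*
outcomes; unconfirmed cancer-free cases are recalled at
`unconfirmed_recall_factor × (1 − spec)` (default 1.5, capped at 1). That
factor is needed because published whole-population recall rates (pooled
≈5.4%) exceed the false-positive rate on confirmed negatives alone (pooled
≈4.0%): the unconfirmed pool contains the harder cases. Without it, no
correlation in [0, 1) can produce a 12.3% human–AI disagreement rate from
the published operating points.

**Dependence.** A Gaussian copula: reader *i* recalls iff a latent standard
normal Zᵢ falls below the quantile of its recall probability, with
correlation `rho_hh` for human–human pairs and `rho_ha` for human–AI pairs,
shared across disease classes (the minimal structure that can match both
observed arbitration rates). The 4×4 correlation matrix is checked for
positive semidefiniteness at construction; infeasible combinations raise a
parameter error.

**Calibration.** `calibrate_arbitration_rate` bisects `rho_hh` and `rho_ha`
against the *closed-form* expected disagreement rate — a mixture of
bivariate-normal orthant probabilities over strata and classes — and then
verifies the result by simulation (default 10⁶ opinion draws, tolerance
±0.2 percentage points, both configurable). Disagreement is strictly
decreasing in the correlation, so bisection is exact; unreachable targets
produce a diagnostic error stating the achievable range. With default
operating points, calibration to the observed 3.3%/12.3% lands near
`rho_hh ≈ 0.93`, `rho_ha ≈ 0.54`.

**Events and censoring.** Outcome events are generated deterministically
from the intended label: detected screen-detectable cancers get malignant
pathology at 7–180 days; interval-type cancers at 181 days to the site's
interval window; followed cancer-free cases get a follow-up read at
1,035–1,150 days. A screen-detectable cancer the historical workflow missed
gets *no* event and surfaces as unconfirmed — reproducing, on purpose, the
retrospective censoring bias by which AI-only detections are measured as
false positives. The omniscient class of every case is available via
`return_truth` for bias studies. Arbitration opinions are generated only
where the historical workflow invokes arbitration, and the recorded final
decision is derived by replaying that workflow, so generated cohorts are
internally consistent by construction (the pipeline-closure test checks that
labelling reproduces the intended category for 100% of cases).

**What the generator does not emulate.** Calendar seasonality and
site-specific temporal drift; reader-specific identities (opinions are
exchangeable within role); arbitration panels vs single arbitrators;
age-dependent prevalence or reader performance; vendor-specific image
appearance (opinions are sampled, not computed from images); and
next-screening-round cancers beyond the interval window. Passing tests on
synthetic cohorts therefore demonstrate the correctness of the pipeline's
logic and statistics under a plausible dependence structure — not the
clinical performance of any AI system on real mammograms.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 20,000–200,000 cases: large enough
that binomial Monte-Carlo error is a fraction of the effects being checked
(at 200,000 cases a per-stratum screen-detectable pool is ~400 cases, giving
~±4 pp sensitivity bands), small enough to run in seconds. Joint assertions
over several binomial checks use Bonferroni-adjusted bands at family level
95%. Calibration verification uses 4×10⁵–10⁶ opinion draws, where ±0.2 pp is
≈4 standard errors of a 3.3% rate. Rounding for display is decimal half-up
(percentages and per-1,000 rates to 1 dp, ratios to 2 dp), applied exactly
once at render time; all stored tables are full precision. Seeds are
explicit everywhere randomness exists; CLI commands refuse to run without
one.

## Known limitations

* Published per-site confidence-interval endpoints and the absolute
  case-assessments-saved figure depend on per-site confirmed/unconfirmed
  counts that are not in the main text of the source evaluation; the package
  computes the analogous quantities from its inputs but cannot reproduce
  those exact printed values.
* The Katz interval treats the two workflows as independent samples although
  they share every case; the paired bootstrap is provided, but a fully
  paired analytic interval (e.g. for correlated binomials) is not
  implemented.
* The generator's single shared correlation per reader-pair type across
  disease classes is the simplest adequate dependence model; real reader
  correlation plausibly differs between cancers and normals.
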