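# dualread

Retrospective evaluation of **double reading in breast cancer screening with
an AI system as the independent second reader**.

Population mammography programmes in much of Europe read every screen twice:
two radiologists give independent recall / no-recall opinions and a third
(the arbitrator) resolves disagreements. Replacing the second human reader
with an AI reader promises large workload savings — if screening performance
is preserved. `dualread` implements the complete retrospective evaluation
pipeline for that question, for biostatisticians and screening-programme
evaluators working with case-level cohort tables:

* **Cohort IO and eligibility** — delimited-text case tables with reader/AI
  opinions and outcome events; 4-view compatibility filtering, date-range
  restriction, seeded participant-level random exclusion, calendar-year
  cohort selection.
* **Ground-truth labelling by follow-up windows** — each case becomes a
  *screen-detected positive* (recalled, malignancy proven within 180 days),
  an *interval cancer* (malignancy within one screening interval: 1,095 days
  for three-year UK programmes, 730 for two-year Hungarian ones), a
  *confirmed negative* (follow-up mammography read ≥ 1,035 days later with no
  malignancy in between), or *unconfirmed*.
* **Workflow simulation** — replay of historical double reading, and
  simulation of double reading with AI: the first reader's opinion is fused
  with the AI's; upon disagreement the historical arbitration opinion is used
  when available, otherwise the historical second reader's opinion stands in.
* **Metrics and testing** — recall rate, cancer detection rate (CDR, per
  1,000), sensitivity, specificity, PPV and arbitration rate on their proper
  denominators, Wilson/Clopper–Pearson 95% CIs, and non-inferiority /
  superiority verdicts on ratios of proportions (Katz log CI, 10% margin,
  one-sided α = 2.5%).
* **Workload model** — relative human reading cost with arbitration reads
  weighted 1–4× a standard read.
* **Synthetic cohorts** — a seeded generator with stratified sites/vendors,
  screening prevalence split into screen-detectable and interval-type
  cancers, censored outcomes, and a Gaussian-copula dependence model for
  correlated reader opinions, calibratable to observed arbitration rates.

## The statistics at the core

For a metric measured as a proportion p̂₁ = k₁/n₁ under double reading with
AI and p̂₀ = k₀/n₀ under historical double reading, the comparison is the
ratio R = p̂₁/p̂₀ with the Katz log-method interval

```
ln R ± 1.96 · sqrt(1/k₁ − 1/n₁ + 1/k₀ − 1/n₀)
```

With non-inferiority margin m = 0.10: for a higher-is-better metric,
non-inferiority requires CI_low > 1 − m and superiority additionally
CI_low > 1; lower-is-better mirrors the rule on CI_high. The workload model
prices a workflow at `base reads + arbitration rate × multiplier` per case,
so automating one of two reads at arbitration rates a₀ → a₁ reduces human
workload by `(2 + a₀·c − 1 − a₁·c) / (2 + a₀·c)` for arbitration cost c.

## Worked example

Calibrate the generator's reader-dependence so disagreement rates match the
observed arbitration rates (3.3% human–human, 12.3% human–AI), generate a
100,000-case cohort, and evaluate it:

```python
from dualread import (SynthParams, calibrate_arbitration_rate,
                      generate_cohort, default_site_configs, evaluate_cohort,
                      render_comparisons)

params, achieved = calibrate_arbitration_rate(
    SynthParams(n_cases=100_000, rng_seed=7), n_check=400_000)
print(achieved)             # {'human_human': 0.0329, 'human_ai': 0.1222}

cases = generate_cohort(params)
report = evaluate_cohort(cases, default_site_configs())
print(report.metrics.query("scope=='pooled' and workflow=='historical_dr'")
      [["metric", "numerator", "denominator", "value"]])
```

prints (abridged):

```
           metric  numerator  denominator    value
      recall_rate       5811       100000 0.058110
              cdr        681       100000 6.810000
      sensitivity        681          815 0.835583
      specificity      28624        29761 0.961796
              ppv        681         5811 0.117192
 arbitration_rate       3273       100000 0.032730
```

i.e. a 5.8% recall rate, 6.8 cancers detected per 1,000 screens, 83.6%
sensitivity on the 815 confirmed positives, and a 3.27% arbitration rate.
The non-inferiority comparison of double reading with AI against the
historical workflow (`render_comparisons(report.comparisons)`) gives

```
     metric      verdict           display
recall_rate non_inferior 0.97 (0.94, 1.01)
        cdr inconclusive 0.98 (0.88, 1.09)
sensitivity non_inferior 0.98 (0.94, 1.03)
specificity non_inferior 1.00 (1.00, 1.01)
        ppv non_inferior 1.01 (0.91, 1.12)
```

(CDR is inconclusive here simply because a 100,000-case cohort carries too
few cancers for the 10% margin), and `report.workload` shows the human
workload falling 44.7% at unit arbitration cost down to 29.9% when
arbitration reads cost four standard reads.

The same pipeline is available from a shell:

```
dualread synth --seed 7 --n-cases 100000 --out cohort/
dualread evaluate cohort/cases.csv --events cohort/events.csv \
    --config config.yaml --out report/
dualread workload --arb-ref 0.033 --arb-cmp 0.123
```

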