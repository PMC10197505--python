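import math

import numpy as np
import pandas as pd
import pytest

from dualread import (classify_verdict, compare_workflows, compute_metrics,
                      katz_ratio_ci, proportion_ci, ratio_comparison,
                      workload_reduction, workload_sweep)
from dualread.ground_truth import GroundTruthLabel
from dualread.stats import (HIGHER_BETTER, INCONCLUSIVE, LOWER_BETTER,
                            NON_INFERIOR, SUPERIOR)

from ._oracles import bootstrap_ratio_ci

R, N = "recall", "no_recall"


def _decisions(finals, disagreements=None):
    n = len(finals)
    return pd.DataFrame({
        "case_id": [f"C{i}" for i in range(n)],
        "workflow": ["historical_dr"] * n,
        "final": finals,
        "arbitrated": [False] * n,
        "resolver": ["agreement"] * n,
        "disagreement": disagreements or [False] * n,
    })


def _labels(categories):
    return {f"C{i}": GroundTruthLabel(cat, None, "fixture")
            for i, cat in enumerate(categories)}


class TestComputeMetrics:
    def test_ten_case_fixture_hand_enumeration(self):
        """2 recalled screen-detected positives, 1 recalled confirmed
        negative, 1 recalled unconfirmed, 6 confirmed negatives not
        recalled."""
        finals = [R, R, R, R] + [N] * 6
        cats = (["screen_detected_positive"] * 2 + ["confirmed_negative"]
                + ["unconfirmed"] + ["confirmed_negative"] * 6)
        out = {m.metric: m for m in compute_metrics(_decisions(finals),
                                                    _labels(cats))}
        assert out["recall_rate"].value == pytest.approx(0.40)
        assert out["cdr"].value == pytest.approx(200.0)  # per 1,000
        assert out["sensitivity"].value == pytest.approx(1.0)
        assert out["specificity"].value == pytest.approx(6 / 7)
        assert out["ppv"].value == pytest.approx(0.50)

    def test_no_recalls_with_one_positive(self):
        out = {m.metric: m for m in compute_metrics(
            _decisions([N] * 5),
            _labels(["interval_cancer"] + ["confirmed_negative"] * 4))}
        assert out["sensitivity"].value == 0.0
        assert out["specificity"].value == 1.0
        assert not out["ppv"].defined  # zero recalls

    def test_undefined_metrics_flagged_not_nan_propagated(self):
        out = {m.metric: m for m in compute_metrics(
            _decisions([N] * 3), _labels(["unconfirmed"] * 3))}
        assert not out["sensitivity"].defined
        assert not out["specificity"].defined
        assert out["recall_rate"].defined

    def test_ppv_algebraic_identity(self, site_configs, small_cohort):
        from dualread import label_cohort, run_workflows
        _, cases, _ = small_cohort
        labels = label_cohort(cases, site_configs)
        table = run_workflows(cases, site_configs)
        sub = table[table.workflow == "dr_with_ai"]
        out = {m.metric: m for m in compute_metrics(sub, labels)}
        assert out["ppv"].value == pytest.approx(
            (out["cdr"].value / 1000.0) / out["recall_rate"].value)

    def test_arbitration_rate_counts_disagreements(self):
        out = {m.metric: m for m in compute_metrics(
            _decisions([N] * 4, disagreements=[True, False, True, False]),
            _labels(["unconfirmed"] * 4))}
        assert out["arbitration_rate"].value == pytest.approx(0.5)

    def test_duplicate_case_rows_rejected(self):
        dup = pd.concat([_decisions([N]), _decisions([N])])
        with pytest.raises(ValueError):
            compute_metrics(dup, _labels(["unconfirmed"]))


class TestProportionCi:
    def test_zero_successes_wilson_closed_form(self):
        low, high = proportion_ci(0, 10, "wilson")
        assert low == 0.0
        # Closed form: upper = z^2 / (n + z^2) at k = 0.
        z = 1.959963984540054
        assert high == pytest.approx(z**2 / (10 + z**2), abs=1e-6)
        assert high == pytest.approx(0.278, abs=1e-3)

    def test_all_successes_upper_bound_one(self):
        low, high = proportion_ci(10, 10, "wilson")
        assert high == 1.0 and low < 1.0

    def test_large_n_interval_matches_printed_style(self):
        # Counts implying a 9.2% recall rate on an 83,410-case stratum give
        # a (9.0%, 9.4%) interval at 1-dp rounding.
        k = round(0.092 * 83410)
        low, high = proportion_ci(k, 83410)
        assert round(100 * low, 1) == 9.0
        assert round(100 * high, 1) == 9.4

    def test_wilson_close_to_clopper_pearson_at_large_n(self):
        for k, n in [(80, 10000), (500, 10000), (9200, 100000)]:
            w = proportion_ci(k, n, "wilson")
            cp = proportion_ci(k, n, "clopper_pearson")
            assert abs(w[0] - cp[0]) < 0.005 and abs(w[1] - cp[1]) < 0.005

    def test_ci_contains_point_estimate(self):
        for k, n in [(0, 10), (3, 7), (10, 10), (123, 456)]:
            low, high = proportion_ci(k, n)
            assert low <= k / n <= high

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 3)


class TestRatioComparison:
    def test_katz_example_frozen_values(self):
        ratio, low, high = katz_ratio_ci(8, 100, 10, 100)
        assert ratio == pytest.approx(0.8)
        # exp(ln 0.8 -/+ 1.96 * sqrt(1/8 - 1/100 + 1/10 - 1/100))
        se = math.sqrt(1 / 8 - 1 / 100 + 1 / 10 - 1 / 100)
        assert low == pytest.approx(0.8 * math.exp(-1.959963984540054 * se))
        assert (round(low, 2), round(high, 2)) == (0.33, 1.94)

    def test_katz_agrees_with_parametric_bootstrap_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n1, n0 = rng.integers(200, 5000, size=2)
            k1 = rng.integers(30, n1 // 2)
            k0 = rng.integers(30, n0 // 2)
            _, lo, hi = katz_ratio_ci(int(k1), int(n1), int(k0), int(n0))
            blo, bhi = bootstrap_ratio_ci(int(k1), int(n1), int(k0), int(n0),
                                          n_rep=100_000, seed=7)
            assert abs(lo - blo) / blo < 0.05
            assert abs(hi - bhi) / bhi < 0.05

    def test_identity_comparison_is_at_least_non_inferior(self):
        res = ratio_comparison(500, 1000, 500, 1000, HIGHER_BETTER)
        assert res.ratio == pytest.approx(1.0)
        assert res.verdict in (NON_INFERIOR, SUPERIOR)
        assert res.verdict == NON_INFERIOR  # CI straddles 1

    def test_zero_comparator_falls_back_to_bootstrap(self):
        res = ratio_comparison(0, 1000, 20, 1000, HIGHER_BETTER, seed=3)
        assert res.ci_method == "bootstrap"
        assert res.verdict == INCONCLUSIVE

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ratio_comparison(5, 100, 0, 100, HIGHER_BETTER)

    def test_verdict_monotone_in_margin_and_ci_width(self):
        # Shrinking the margin never upgrades; widening the CI never upgrades.
        rank = {INCONCLUSIVE: 0, NON_INFERIOR: 1, SUPERIOR: 2}
        for lo, hi in [(0.85, 0.95), (0.92, 1.02), (1.01, 1.05), (0.7, 1.3)]:
            for orient in (HIGHER_BETTER, LOWER_BETTER):
                v_wide_margin = classify_verdict(lo, hi, orient, margin=0.10)
                v_narrow_margin = classify_verdict(lo, hi, orient, margin=0.02)
                assert rank[v_narrow_margin] <= rank[v_wide_margin]
                v_wider_ci = classify_verdict(lo - 0.05, hi + 0.05, orient,
                                              margin=0.10)
                assert rank[v_wider_ci] <= rank[v_wide_margin]

    def test_orientation_symmetry_under_reciprocal_margin(self):
        # A lower-is-better verdict on (lo, hi) equals the higher-is-better
        # verdict on the inverted interval (1/hi, 1/lo).
        for lo, hi in [(0.85, 0.95), (0.9, 1.05), (1.02, 1.2), (0.99, 1.09)]:
            v_lower = classify_verdict(lo, hi, LOWER_BETTER, margin=0.10,
                                       margin_rule="reciprocal")
            v_higher = classify_verdict(1 / hi, 1 / lo, HIGHER_BETTER,
                                        margin=0.10)
            assert v_lower == v_higher


class TestCompareWorkflows:
    def _metrics(self, recalls, n=10_000, positives=90, tp=80, negatives=5000):
        from dualread.stats import _estimate
        return [
            _estimate("recall_rate", recalls, n, "wilson"),
            _estimate("cdr", tp, n, "wilson", scale=1000.0),
            _estimate("sensitivity", tp, positives, "wilson"),
            _estimate("specificity", negatives - recalls + tp, negatives, "wilson"),
            _estimate("ppv", tp, recalls, "wilson"),
        ]

    def test_identical_tables_give_unit_ratios(self):
        a = self._metrics(400)
        results = compare_workflows(a, a)
        assert results and all(r.ratio == pytest.approx(1.0) for r in results)

    def test_mismatched_cohorts_rejected(self):
        with pytest.raises(ValueError):
            compare_workflows(self._metrics(400, n=10_000),
                              self._metrics(400, n=9_000))

    def test_default_orientations(self):
        results = {r.metric: r for r in
                   compare_workflows(self._metrics(300), self._metrics(400))}
        assert results["recall_rate"].orientation == LOWER_BETTER
        assert results["sensitivity"].orientation == HIGHER_BETTER


class TestWorkload:
    def test_published_endpoints(self):
        low = workload_reduction(0.033, 0.123, multiplier=4.0)
        high = workload_reduction(0.033, 0.123, multiplier=1.0)
        assert round(100 * low.reduction, 1) == 30.0
        assert round(100 * high.reduction, 1) == 44.8

    def test_equal_rates_give_half(self):
        est = workload_reduction(0.0, 0.0, multiplier=1.0)
        assert est.reduction == pytest.approx(0.5)
        est = workload_reduction(0.07, 0.07, multiplier=3.0)
        assert est.reduction == pytest.approx((2 - 1) / (2 + 0.21))

    def test_negative_reduction_reported_not_raised(self):
        est = workload_reduction(0.0, 0.9, multiplier=4.0, reads_cmp=2.0)
        assert est.reduction < 0

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            workload_reduction(0.033, 0.123, multiplier=0.5)

    def test_sweep_is_monotone_when_arbitration_grows(self):
        table = workload_sweep(0.033, 0.123, [1.0, 2.0, 3.0, 4.0])
        assert list(table["reduction"]) == sorted(table["reduction"],
                                                  reverse=True)

    def test_assessments_saved_reported_with_cohort_size(self):
        est = workload_reduction(0.033, 0.123, 1.0, cohort_size=275_900)
        assert est.assessments_saved == pytest.approx(
            275_900 * (1 - 0.09), rel=1e-6)
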