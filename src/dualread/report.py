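"""End-to-end evaluation pipeline, report tables, and declarative config.

`evaluate_cohort` chains labelling, workflow replay/simulation, metrics,
workflow comparison, and the workload model, and returns full-precision
tables. Rendering to the conventional printed precision (percentages and
per-1,000 rates to 1 decimal place, ratios to 2) happens once, at render
time, with half-up rounding — report cells are otherwise exactly the
module-level numbers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CaseRecord, CohortSelection, SiteConfig
from .ground_truth import label_cohort, summarize_labels
from .stats import (DEFAULT_ORIENTATIONS, compare_workflows, compute_metrics,
                    workload_sweep)
from .workflow import DR_WITH_AI, HISTORICAL_DR, WORKFLOWS, run_workflows


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables;
    Python's built-in round is half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(p: float, decimals: int = 1) -> str:
    return f"{round_half_up(100.0 * p, decimals):.{decimals}f}%"


def format_per_thousand(v: float, decimals: int = 1) -> str:
    return f"{round_half_up(v, decimals):.{decimals}f} per 1000"


def format_ratio(r: float, decimals: int = 2) -> str:
    return f"{round_half_up(r, decimals):.{decimals}f}"


@dataclass
class EvaluationReport:
    """Full-precision tables produced by one evaluation run."""

    labels: pd.DataFrame        # category counts/proportions per scope
    metrics: pd.DataFrame       # scope x workflow x metric estimates
    comparisons: pd.DataFrame   # DR-with-AI vs historical DR ratio tests
    workload: pd.DataFrame      # arbitration-cost multiplier sweep
    flow: pd.DataFrame          # STARD-style case counts per pipeline stage


def _scopes(cases: Sequence[CaseRecord]) -> dict[str, list[CaseRecord]]:
    scopes: dict[str, list[CaseRecord]] = {"pooled": list(cases)}
    for c in cases:
        scopes.setdefault(f"site:{c.site}", []).append(c)
        scopes.setdefault(f"region:{c.region}", []).append(c)
    return scopes


def evaluate_cohort(
    cases: Sequence[CaseRecord],
    site_configs: Mapping[str, SiteConfig],
    ci_method: str = "wilson",
    margin: float = 0.10,
    multipliers: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
) -> EvaluationReport:
    """Run labelling, all four workflows, metrics, comparisons and workload.

    Metrics and comparisons are produced pooled, per site, and per region;
    the comparison is double reading with AI (comparator) against historical
    double reading (reference).
    """
    if not cases:
        raise ValueError("cannot evaluate an empty cohort")
    labels = label_cohort(cases, dict(site_configs))
    decisions = run_workflows(cases, dict(site_configs))

    label_rows, metric_rows, cmp_rows, workload_frames = [], [], [], []
    for scope, scope_cases in _scopes(cases).items():
        ids = {c.case_id for c in scope_cases}
        scope_labels = {cid: labels[cid] for cid in ids}
        summary = summarize_labels([labels[c.case_id] for c in scope_cases])
        summary.insert(0, "scope", scope)
        label_rows.append(summary.drop(columns="stratum"))

        per_wf = {}
        for wf in WORKFLOWS:
            sub = decisions[(decisions["workflow"] == wf)
                            & decisions["case_id"].isin(ids)]
            estimates = compute_metrics(sub, scope_labels, ci_method)
            per_wf[wf] = estimates
            for m in estimates:
                metric_rows.append({
                    "scope": scope, "workflow": wf, "metric": m.metric,
                    "numerator": m.numerator, "denominator": m.denominator,
                    "value": m.value, "ci_low": m.ci_low, "ci_high": m.ci_high,
                    "ci_method": m.ci_method, "defined": m.defined,
                })
        for r in compare_workflows(per_wf[DR_WITH_AI], per_wf[HISTORICAL_DR],
                                   margin=margin):
            cmp_rows.append({
                "scope": scope, "metric": r.metric,
                "orientation": r.orientation, "ratio": r.ratio,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "margin": r.margin, "verdict": r.verdict,
            })
        arb = {wf: next(m for m in per_wf[wf] if m.metric == "arbitration_rate")
               for wf in (HISTORICAL_DR, DR_WITH_AI)}
        sweep = workload_sweep(arb[HISTORICAL_DR].proportion,
                               arb[DR_WITH_AI].proportion, multipliers)
        sweep.insert(0, "scope", scope)
        workload_frames.append(sweep)

    flow = pd.DataFrame([
        {"stage": "evaluated_cases", "count": len(cases)},
        {"stage": "workflows", "count": len(WORKFLOWS)},
        {"stage": "decision_rows", "count": len(decisions)},
    ])
    return EvaluationReport(
        labels=pd.concat(label_rows, ignore_index=True),
        metrics=pd.DataFrame(metric_rows),
        comparisons=pd.DataFrame(cmp_rows),
        workload=pd.concat(workload_frames, ignore_index=True),
        flow=flow,
    )


def render_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Printed-precision view of a metrics table (value with 95% CI)."""
    rows = []
    for r in metrics.to_dict("records"):
        if not r.get("defined", True):
            text = "undefined"
        elif r["metric"] == "cdr":
            text = (f"{format_per_thousand(r['value'])} "
                    f"({round_half_up(r['ci_low'], 1):.1f}, "
                    f"{round_half_up(r['ci_high'], 1):.1f})")
        else:
            text = (f"{format_percent(r['value'])} "
                    f"({round_half_up(100 * r['ci_low'], 1):.1f}, "
                    f"{round_half_up(100 * r['ci_high'], 1):.1f})")
        rows.append({"scope": r["scope"], "workflow": r["workflow"],
                     "metric": r["metric"], "display": text,
                     "numerator": r["numerator"],
                     "denominator": r["denominator"]})
    return pd.DataFrame(rows)


def render_comparisons(comparisons: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in comparisons.to_dict("records"):
        rows.append({
            "scope": r["scope"], "metric": r["metric"],
            "verdict": r["verdict"],
            "display": (f"{format_ratio(r['ratio'])} "
                        f"({format_ratio(r['ci_low'])}, "
                        f"{format_ratio(r['ci_high'])})"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Declarative configuration
# ---------------------------------------------------------------------------

def site_configs_from_dict(cfg: Mapping) -> dict[str, SiteConfig]:
    """SiteConfig entries from a parsed declarative config (``sites:`` list)."""
    out = {}
    for entry in cfg.get("sites", []):
        sc = SiteConfig(
            site=entry["site"], region=entry["region"],
            screening_interval_days=int(entry["screening_interval_days"]),
            arbitrate_agreed_recalls=bool(entry.get("arbitrate_agreed_recalls", False)),
            negative_followup_min_days=int(entry.get("negative_followup_min_days", 1035)),
            screen_detect_window_days=int(entry.get("screen_detect_window_days", 180)),
        )
        out[sc.site] = sc
    return out


def selection_from_dict(cfg: Mapping) -> CohortSelection | None:
    """CohortSelection from the ``selection:`` section, if present."""
    sel = cfg.get("selection")
    if sel is None:
        return None
    return CohortSelection(
        name=sel.get("name", "selection"),
        date_range=(dt.date.fromisoformat(sel["date_start"]),
                    dt.date.fromisoformat(sel["date_end"])),
        excluded_participant_fraction=float(
            sel.get("excluded_participant_fraction", 0.0)),
        rng_seed=int(sel["rng_seed"]),
    )
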