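"""Outcome labelling: the four-way partition of screening cases.

Every case falls in exactly one category:

* ``screen_detected_positive`` — recalled by the historical workflow with a
  pathology-proven malignancy within the screen-detection window (180 days);
* ``interval_cancer`` — a pathology-proven malignancy within one screening
  interval of the screen (1,095 days UK / 730 days HU) that was not
  screen-detected;
* ``confirmed_negative`` — a follow-up mammography read at least 1,035 days
  after screening with no malignancy proven before it;
* ``unconfirmed`` — everything else. Unconfirmed cases stay in the cohort and
  count in whole-population metrics (recall rate, CDR, arbitration rate).

Categories are assigned in that order of precedence, so a recalled cancer
confirmed within the detection window is never double-counted as an interval
cancer. Window comparisons are on whole-day differences, inclusive of the
boundary day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cohort import RECALL, CaseRecord, SiteConfig

SCREEN_DETECTED = "screen_detected_positive"
INTERVAL_CANCER = "interval_cancer"
CONFIRMED_NEGATIVE = "confirmed_negative"
UNCONFIRMED = "unconfirmed"
CATEGORIES = (SCREEN_DETECTED, INTERVAL_CANCER, CONFIRMED_NEGATIVE, UNCONFIRMED)

POSITIVE_CATEGORIES = frozenset({SCREEN_DETECTED, INTERVAL_CANCER})


@dataclass(frozen=True)
class GroundTruthLabel:
    """Category, the event date that decided it, and a reason code."""

    category: str
    evidence_date: dt.date | None
    rationale: str


def label_case(case: CaseRecord, cfg: SiteConfig) -> GroundTruthLabel:
    """Assign the outcome category for one case under a site's windows.

    Total function: any validated case receives exactly one label.
    """
    malignant = sorted(
        (ev.date for ev in case.pathology_events if ev.malignant))
    first_malignant = malignant[0] if malignant else None

    if case.historical_final == RECALL and first_malignant is not None:
        days = (first_malignant - case.screening_date).days
        if days <= cfg.screen_detect_window_days:
            return GroundTruthLabel(
                SCREEN_DETECTED, first_malignant,
                f"recalled_malignancy_within_{cfg.screen_detect_window_days}d")

    if first_malignant is not None:
        days = (first_malignant - case.screening_date).days
        if days <= cfg.ic_window_days:
            # Includes the corner case of a historically recalled case whose
            # first malignancy falls after the detection window: the recall
            # did not yield a confirmed diagnosis in time, so it counts as an
            # interval cancer.
            return GroundTruthLabel(
                INTERVAL_CANCER, first_malignant,
                f"malignancy_within_ic_window_{cfg.ic_window_days}d")

    for followup in sorted(case.followup_mammograms):
        days = (followup - case.screening_date).days
        if days >= cfg.negative_followup_min_days:
            # Malignancy proven before the qualifying read blocks negativity,
            # even if it lies outside the IC window (e.g. an HU malignancy
            # after 730 days): such a case stays unconfirmed.
            if first_malignant is None or first_malignant > followup:
                return GroundTruthLabel(
                    CONFIRMED_NEGATIVE, followup,
                    f"negative_followup_ge_{cfg.negative_followup_min_days}d")
            break

    return GroundTruthLabel(UNCONFIRMED, None, "no_qualifying_outcome_evidence")


def label_cohort(
    cases: Sequence[CaseRecord],
    site_configs: dict[str, SiteConfig],
) -> dict[str, GroundTruthLabel]:
    """Labels keyed by case_id, using each case's own site configuration."""
    return {c.case_id: label_case(c, site_configs[c.site]) for c in cases}


def summarize_labels(
    labels: Iterable[GroundTruthLabel],
    strata: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Counts and whole-cohort proportions per category (optionally by stratum).

    Proportions always use the full cohort (or full stratum) as denominator,
    matching how population characteristics are tabulated.
    """
    labels = list(labels)
    if strata is None:
        strata_list = ["all"] * len(labels)
    else:
        strata_list = list(strata)
        if len(strata_list) != len(labels):
            raise ValueError("strata must align with labels")
    df = pd.DataFrame({"stratum": strata_list,
                       "category": [l.category for l in labels]})
    rows = []
    for stratum in dict.fromkeys(strata_list) if labels else ["all"]:
        sub = df[df["stratum"] == stratum] if labels else df
        n = len(sub)
        for cat in CATEGORIES:
            k = int((sub["category"] == cat).sum())
            rows.append({"stratum": stratum, "category": cat, "count": k,
                         "proportion": (k / n) if n else 0.0})
    return pd.DataFrame(rows, columns=["stratum", "category", "count", "proportion"])
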