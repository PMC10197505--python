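"""Decision fusion: replaying human double reading and simulating double
reading with an AI second reader.

Historical double reading: two human readers give independent recall /
no-recall opinions. Agreement on "no recall" is final; agreement on "recall"
is final unless the site's local practice also arbitrates agreed recalls;
disagreement goes to arbitration. Double reading with AI keeps the historical
first reader and replaces the second reader with the AI's opinion; upon
disagreement the historical arbitration opinion is used when it exists,
otherwise the historical second reader's opinion stands in for the arbitrator
(which, in such circumstances, coincides with the first reader's opinion
whenever no historical arbitration took place).

Arbitration rate is defined as the rate of disagreement between the two
readers of the workflow (first vs second historically, first vs AI in
simulation); the ``arbitrated`` flag additionally covers agreed-recall
arbitrations under sites that practise them, and both are carried in the
trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cohort import NO_RECALL, RECALL, CaseRecord, SiteConfig

logger = logging.getLogger("dualread")

HISTORICAL_DR = "historical_dr"
DR_WITH_AI = "dr_with_ai"
STANDALONE_AI = "standalone_ai"
FIRST_READER_ONLY = "first_reader_only"
WORKFLOWS = (HISTORICAL_DR, DR_WITH_AI, STANDALONE_AI, FIRST_READER_ONLY)

# How the final decision was reached.
AGREEMENT = "agreement"
HISTORICAL_ARBITRATION = "historical_arbitration"
SECOND_READER_SUBSTITUTE = "second_reader_substitute"
POLICY_RECALL = "policy_recall"


class FusionError(ValueError):
    """A disagreement cannot be resolved from the available opinions."""


@dataclass(frozen=True)
class DecisionTrace:
    """Final decision of one workflow on one case, with provenance."""

    workflow: str
    final: str
    arbitrated: bool
    resolver: str
    disagreement: bool


def replay_historical(case: CaseRecord, cfg: SiteConfig) -> DecisionTrace:
    """Replay the recorded human double-reading decision for one case."""
    disagreement = case.r1 != case.r2
    if not disagreement:
        if case.r1 == NO_RECALL:
            return DecisionTrace(HISTORICAL_DR, NO_RECALL, False, AGREEMENT, False)
        if not cfg.arbitrate_agreed_recalls:
            return DecisionTrace(HISTORICAL_DR, RECALL, False, AGREEMENT, False)
        # Agreed recall at a site that arbitrates agreed recalls.
        final = case.arbitration if case.arbitration is not None else case.historical_final
        return DecisionTrace(HISTORICAL_DR, final, True, POLICY_RECALL, False)
    if case.arbitration is not None:
        return DecisionTrace(HISTORICAL_DR, case.arbitration, True,
                             HISTORICAL_ARBITRATION, True)
    if case.historical_final is not None:
        # The recorded final decision embeds the historical arbitration outcome.
        return DecisionTrace(HISTORICAL_DR, case.historical_final, True,
                             HISTORICAL_ARBITRATION, True)
    raise FusionError(
        f"case {case.case_id}: reader disagreement with no arbitration "
        "opinion and no recorded final decision")


def simulate_dr_with_ai(case: CaseRecord, cfg: SiteConfig) -> DecisionTrace:
    """Fuse the historical first reader with the AI as independent second reader.

    Agreement (in either direction) is final and never arbitrated — the
    agreed-recall arbitration policy belongs to the historical workflow only.
    """
    disagreement = case.r1 != case.ai
    if not disagreement:
        return DecisionTrace(DR_WITH_AI, case.r1, False, AGREEMENT, False)
    if case.arbitration is not None:
        return DecisionTrace(DR_WITH_AI, case.arbitration, True,
                             HISTORICAL_ARBITRATION, True)
    if case.r2 is not None:
        return DecisionTrace(DR_WITH_AI, case.r2, True,
                             SECOND_READER_SUBSTITUTE, True)
    raise FusionError(
        f"case {case.case_id}: first reader / AI disagreement with no "
        "arbitration opinion and no second reader opinion")


def run_workflows(
    cases: Sequence[CaseRecord],
    cfg_map: Mapping[str, SiteConfig],
    check_replay: bool = True,
) -> pd.DataFrame:
    """Decision traces for every case under all four workflows.

    Returns one row per case per workflow with columns
    ``case_id, workflow, final, arbitrated, resolver, disagreement``.

    When the replayed historical decision contradicts the recorded
    ``historical_final``, the recorded value wins (it is the workflow outcome
    that actually happened) and the discrepancy is logged as a data-quality
    warning.
    """
    rows = []
    n_mismatch = 0
    for case in cases:
        cfg = cfg_map[case.site]
        hist = replay_historical(case, cfg)
        if check_replay and hist.final != case.historical_final:
            n_mismatch += 1
            logger.warning(
                "case %s: replayed historical decision %s contradicts recorded "
                "final %s; keeping the recorded value",
                case.case_id, hist.final, case.historical_final)
            hist = DecisionTrace(HISTORICAL_DR, case.historical_final,
                                 hist.arbitrated, hist.resolver, hist.disagreement)
        rows.append(_row(case, hist))
        rows.append(_row(case, simulate_dr_with_ai(case, cfg)))
        rows.append(_row(case, DecisionTrace(
            STANDALONE_AI, case.ai, False, AGREEMENT, False)))
        rows.append(_row(case, DecisionTrace(
            FIRST_READER_ONLY, case.r1, False, AGREEMENT, False)))
    if n_mismatch:
        logger.warning("%d case(s) had replay/recorded mismatches", n_mismatch)
    return pd.DataFrame(
        rows,
        columns=["case_id", "workflow", "final", "arbitrated", "resolver",
                 "disagreement"],
    )


def _row(case: CaseRecord, trace: DecisionTrace) -> dict:
    return {"case_id": case.case_id, "workflow": trace.workflow,
            "final": trace.final, "arbitrated": trace.arbitrated,
            "resolver": trace.resolver, "disagreement": trace.disagreement}
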