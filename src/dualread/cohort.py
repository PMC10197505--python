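"""Case-level cohort data model, delimited-text IO, and eligibility filtering.

A *case* is one screening episode: the mammogram, the independent opinions of
the first and second human readers (and, where invoked, an arbitrator), the
binary opinion of an AI reader, and the outcome events observed afterwards
(pathology results and follow-up mammograms). Cohorts are plain delimited-text
tables; outcome events travel in a companion long-format table keyed by
``case_id``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dualread")

RECALL = "recall"
NO_RECALL = "no_recall"
OPINIONS = frozenset({RECALL, NO_RECALL})

#: Default sites shipped with the package: three UK NHSBSP centres on a
#: three-year screening interval and one Hungarian centre on a two-year
#: interval. Users may register additional sites via :class:`SiteConfig`.
DEFAULT_SITES = ("LTHT", "NUH", "ULH", "MK")

CASE_COLUMNS = [
    "case_id", "participant_id", "site", "vendor", "region",
    "screening_date", "age_years", "r1", "r2", "arbitration",
    "historical_final", "ai", "n_views",
]
EVENT_COLUMNS = ["case_id", "event_type", "date", "malignant", "proven_by"]

MANDATORY_COLUMNS = [c for c in CASE_COLUMNS if c != "arbitration"]


class SchemaError(ValueError):
    """A mandatory column is missing or the file cannot be interpreted."""


@dataclass(frozen=True)
class PathologyEvent:
    """A pathology result: the date it was proven and whether it was malignant.

    ``proven_by`` carries the modality (FNAC, CNB, VACB, histology, ...) as
    free text; it never influences labelling.
    """

    date: dt.date
    malignant: bool
    proven_by: str = ""


@dataclass
class CaseRecord:
    """One screening episode with reader opinions and outcome events."""

    case_id: str
    participant_id: str
    site: str
    vendor: str
    region: str
    screening_date: dt.date
    age_years: int
    r1: str
    r2: str
    historical_final: str
    ai: str
    arbitration: str | None = None
    pathology_events: list[PathologyEvent] = field(default_factory=list)
    followup_mammograms: list[dt.date] = field(default_factory=list)
    n_views: int = 4

    def validate(self) -> None:
        for name in ("r1", "r2", "historical_final", "ai"):
            value = getattr(self, name)
            if value not in OPINIONS:
                raise ValueError(
                    f"case {self.case_id}: {name}={value!r} not in {sorted(OPINIONS)}"
                )
        if self.arbitration is not None and self.arbitration not in OPINIONS:
            raise ValueError(
                f"case {self.case_id}: arbitration={self.arbitration!r} invalid"
            )
        if self.age_years < 0:
            raise ValueError(f"case {self.case_id}: negative age")
        for ev in self.pathology_events:
            if ev.date < self.screening_date:
                raise ValueError(
                    f"case {self.case_id}: pathology event {ev.date} predates screening"
                )
        for d in self.followup_mammograms:
            if d < self.screening_date:
                raise ValueError(
                    f"case {self.case_id}: follow-up mammogram {d} predates screening"
                )


@dataclass(frozen=True)
class SiteConfig:
    """Per-site screening policy and ground-truth windows (whole days).

    ``ic_window_days`` equals the screening interval: interval cancers are
    malignancies proven within one interval of the screen (1,095 days for the
    UK three-year programmes, 730 days for the Hungarian two-year programme).
    A negative is confirmed by a follow-up mammography read at least
    ``negative_followup_min_days`` (default 1,035, two months short of a
    three-year interval) after screening with no malignancy proven in between.
    All "within N days" comparisons are inclusive of day N.
    """

    site: str
    region: str
    screening_interval_days: int
    arbitrate_agreed_recalls: bool = False
    negative_followup_min_days: int = 1035
    screen_detect_window_days: int = 180

    def __post_init__(self) -> None:
        for name in ("screening_interval_days", "negative_followup_min_days",
                     "screen_detect_window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ic_window_days(self) -> int:
        return self.screening_interval_days


def default_site_configs(arbitrate_agreed_recalls: bool = False) -> dict[str, SiteConfig]:
    """The four study sites: UK centres (3-year interval) and MK (2-year)."""
    cfg = {
        s: SiteConfig(site=s, region="UK", screening_interval_days=1095,
                      arbitrate_agreed_recalls=arbitrate_agreed_recalls)
        for s in ("LTHT", "NUH", "ULH")
    }
    cfg["MK"] = SiteConfig(site="MK", region="HU", screening_interval_days=730,
                           arbitrate_agreed_recalls=arbitrate_agreed_recalls)
    return cfg


@dataclass(frozen=True)
class CohortSelection:
    """Eligibility filter: date range plus a random participant-level exclusion."""

    name: str
    date_range: tuple[dt.date, dt.date]
    excluded_participant_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.excluded_participant_fraction < 1.0:
            raise ValueError("excluded_participant_fraction must be in [0, 1)")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start after end")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(str(text).strip())


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_cohort(
    path: str | Path,
    events_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Read a cohort table (and optional events table) into validated records.

    Parameters
    ----------
    path
        Delimited text file (comma default, tab for ``.tsv``) with a header.
    events_path
        Optional long-format events table with columns
        ``case_id, event_type, date, malignant, proven_by`` where
        ``event_type`` is ``pathology`` or ``followup_mammogram``.
    schema
        Mapping from canonical column names to the file's column names, for
        files using different headers.

    Returns
    -------
    (records, errors)
        Validated records and a table of row-level validation failures
        (``row``, ``case_id``, ``error``). Invalid rows are reported, never
        silently dropped into the output.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if "arbitration" not in df.columns:
        df["arbitration"] = ""

    events_by_case: dict[str, list[dict]] = {}
    if events_path is not None:
        events_path = Path(events_path)
        ev = pd.read_csv(events_path, sep=_sep_for(events_path), dtype=str,
                         keep_default_na=False)
        missing_ev = [c for c in ("case_id", "event_type", "date") if c not in ev.columns]
        if missing_ev:
            raise SchemaError(
                f"{events_path}: missing mandatory column(s): {', '.join(missing_ev)}"
            )
        for row in ev.to_dict("records"):
            events_by_case.setdefault(str(row["case_id"]), []).append(row)

    records: list[CaseRecord] = []
    errors: list[dict] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(_row_to_record(row, events_by_case))
        except (ValueError, KeyError) as exc:
            errors.append({"row": i, "case_id": row.get("case_id", ""), "error": str(exc)})
            logger.warning("row %d (case %s) rejected: %s", i, row.get("case_id", ""), exc)
    return records, pd.DataFrame(errors, columns=["row", "case_id", "error"])


def _row_to_record(row: Mapping[str, str], events_by_case: Mapping[str, list[dict]]) -> CaseRecord:
    arb = str(row["arbitration"]).strip()
    case = CaseRecord(
        case_id=str(row["case_id"]),
        participant_id=str(row["participant_id"]),
        site=str(row["site"]),
        vendor=str(row["vendor"]),
        region=str(row["region"]),
        screening_date=_parse_date(row["screening_date"]),
        age_years=int(row["age_years"]),
        r1=str(row["r1"]).strip(),
        r2=str(row["r2"]).strip(),
        arbitration=arb or None,
        historical_final=str(row["historical_final"]).strip(),
        ai=str(row["ai"]).strip(),
        n_views=int(row["n_views"]),
    )
    for ev in events_by_case.get(case.case_id, []):
        kind = str(ev["event_type"]).strip()
        date = _parse_date(ev["date"])
        if kind == "pathology":
            malignant = str(ev.get("malignant", "")).strip().lower() in {"true", "1", "yes"}
            case.pathology_events.append(
                PathologyEvent(date=date, malignant=malignant,
                               proven_by=str(ev.get("proven_by", "")))
            )
        elif kind == "followup_mammogram":
            case.followup_mammograms.append(date)
        else:
            raise ValueError(f"unknown event_type {kind!r}")
    case.pathology_events.sort(key=lambda e: e.date)
    case.followup_mammograms.sort()
    case.validate()
    return case


def write_cohort(
    cases: Iterable[CaseRecord],
    path: str | Path,
    events_path: str | Path | None = None,
) -> None:
    """Write cases (and, if a path is given, their events) as delimited text."""
    path = Path(path)
    rows, event_rows = [], []
    for c in cases:
        rows.append({
            "case_id": c.case_id, "participant_id": c.participant_id,
            "site": c.site, "vendor": c.vendor, "region": c.region,
            "screening_date": c.screening_date.isoformat(),
            "age_years": c.age_years, "r1": c.r1, "r2": c.r2,
            "arbitration": c.arbitration or "",
            "historical_final": c.historical_final, "ai": c.ai,
            "n_views": c.n_views,
        })
        for ev in c.pathology_events:
            event_rows.append({
                "case_id": c.case_id, "event_type": "pathology",
                "date": ev.date.isoformat(),
                "malignant": str(ev.malignant).lower(), "proven_by": ev.proven_by,
            })
        for d in c.followup_mammograms:
            event_rows.append({
                "case_id": c.case_id, "event_type": "followup_mammogram",
                "date": d.isoformat(), "malignant": "", "proven_by": "",
            })
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)
    if events_path is not None:
        events_path = Path(events_path)
        pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(
            events_path, sep=_sep_for(events_path), index=False)


# ---------------------------------------------------------------------------
# Eligibility filtering and cohort selection
# ---------------------------------------------------------------------------

def filter_eligible(
    cases: Sequence[CaseRecord],
    selection: CohortSelection,
) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Apply the eligibility flow: 4-view compatibility, date range, then
    exclusion of every case from a randomly drawn fraction of participants.

    The participant draw is exact-count sampling without replacement over the
    sorted participant universe, seeded by ``selection.rng_seed``; the
    exclusion log records one row per removed case, in flow order, with the
    generator name and seed so the flow is reproducible.
    """
    log_rows: list[dict] = []
    step1: list[CaseRecord] = []
    for c in cases:
        if c.n_views != 4:
            log_rows.append(_log_row(c, 1, "incompatible_views"))
        else:
            step1.append(c)

    start, end = selection.date_range
    step2: list[CaseRecord] = []
    for c in step1:
        if start <= c.screening_date <= end:
            step2.append(c)
        else:
            log_rows.append(_log_row(c, 2, "out_of_date_range"))

    participants = sorted({c.participant_id for c in step2})
    n_excl = int(round(selection.excluded_participant_fraction * len(participants)))
    excluded: frozenset[str] = frozenset()
    if n_excl > 0:
        rng = np.random.default_rng(selection.rng_seed)
        excluded = frozenset(rng.choice(participants, size=n_excl, replace=False))
    kept: list[CaseRecord] = []
    for c in step2:
        if c.participant_id in excluded:
            log_rows.append(_log_row(c, 3, "random_participant_exclusion"))
        else:
            kept.append(c)

    if not kept:
        logger.warning("selection %r kept no cases", selection.name)
    log = pd.DataFrame(
        log_rows, columns=["case_id", "participant_id", "step", "reason"])
    log.attrs["rng"] = f"numpy.default_rng(seed={selection.rng_seed})"
    return kept, log


def _log_row(case: CaseRecord, step: int, reason: str) -> dict:
    return {"case_id": case.case_id, "participant_id": case.participant_id,
            "step": step, "reason": reason}


def select_year_cohort(cases: Sequence[CaseRecord], year: int) -> list[CaseRecord]:
    """Cases screened within one calendar year (the single-year cohort)."""
    return [c for c in cases if c.screening_date.year == year]


def clone_case(case: CaseRecord, **changes) -> CaseRecord:
    """A modified copy of a case (lists are copied, not shared)."""
    new = replace(case, **changes)
    if "pathology_events" not in changes:
        new.pathology_events = list(case.pathology_events)
    if "followup_mammograms" not in changes:
        new.followup_mammograms = list(case.followup_mammograms)
    return new
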