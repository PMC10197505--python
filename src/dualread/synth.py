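"""Synthetic screening cohorts with the population structure the analysis
assumes: stratified sites/vendors, realistic age mix, screening-prevalence
positives split into screen-detectable and interval-type cancers, a large
unconfirmed fraction, and correlated reader/AI opinions.

Opinion model
-------------
Each case carries a latent disease class: *screen-detectable cancer* (a cancer
a competent reader can find on the mammogram), *interval-type cancer* (a
cancer that will surface clinically within one screening interval but is
radiologically occult at screening), or *cancer-free*. Conditional on the
class, the four readers (first human reader, second human reader, arbitrator,
AI) each recall with a class- and stratum-specific probability: `sens` on
screen-detectable cancers, `ic_hit` on interval-type cancers (humans find few
of these; the AI finds more), and `1 - spec` on cancer-free cases. Dependence
between readers is a Gaussian copula: reader *i* recalls iff a latent standard
normal Z_i falls below the quantile of its recall probability, with
correlation ``rho_hh`` between human pairs and ``rho_ha`` between each human
and the AI, shared across disease classes.

Cancer-free cases that will never receive a qualifying follow-up read (the
unconfirmed majority) are recalled more often than confirmed negatives, by a
configurable factor: in screening data the unconfirmed pool contains the
harder cases, and published whole-population recall rates exceed the
false-positive rate measured on confirmed negatives alone.

Outcome events are generated deterministically from the intended label, and
retrospective censoring is reproduced on purpose: a screen-detectable cancer
the historical workflow missed gets *no* pathology event and surfaces as
unconfirmed, so an AI recall on it is measured as a false positive — the bias
inherent to retrospective evaluation. Set ``return_truth`` to obtain the
omniscient class of every case for bias studies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from .cohort import NO_RECALL, RECALL, CaseRecord, PathologyEvent

READERS = ("r1", "r2", "arb", "ai")

# Latent disease classes / intended labels.
SD_CANCER = "screen_detectable"
IC_CANCER = "interval_type"
CANCER_FREE = "cancer_free"


class ParameterError(ValueError):
    """Generative parameters are inconsistent or infeasible."""


@dataclass(frozen=True)
class OperatingPoint:
    """Recall probabilities of one reader in one stratum, by disease class."""

    sens: float      # P(recall | screen-detectable cancer)
    spec: float      # P(no recall | cancer-free)
    ic_hit: float    # P(recall | interval-type cancer)

    def __post_init__(self) -> None:
        for name in ("sens", "spec", "ic_hit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"operating point {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class StratumSpec:
    """One site/vendor stratum: its weight and per-reader operating points."""

    site: str
    vendor: str
    region: str
    proportion: float
    r1: OperatingPoint
    r2: OperatingPoint
    arb: OperatingPoint
    ai: OperatingPoint

    def op(self, reader: str) -> OperatingPoint:
        return getattr(self, reader)


def _stratum(site, vendor, region, prop, r1, ai) -> StratumSpec:
    arb = OperatingPoint(min(0.99, r1.sens + 0.05), r1.spec, 0.15)
    return StratumSpec(site, vendor, region, prop, r1=r1, r2=r1, arb=arb, ai=ai)


def default_strata() -> list[StratumSpec]:
    """The four study strata with published stratum weights and per-stratum
    reader/AI operating points (first-reader and standalone-AI ten-year
    values); second readers are assumed comparable to first readers and
    arbitrators slightly more sensitive, neither being published."""
    return [
        _stratum("MK", "IMS_Giotto", "HU", 83410 / 275900,
                 OperatingPoint(0.794, 0.954, 0.07),
                 OperatingPoint(0.857, 0.961, 0.30)),
        _stratum("NUH", "GE", "UK", 69045 / 275900,
                 OperatingPoint(0.778, 0.973, 0.07),
                 OperatingPoint(0.769, 0.896, 0.30)),
        _stratum("LTHT", "Hologic", "UK", 64645 / 275900,
                 OperatingPoint(0.810, 0.950, 0.07),
                 OperatingPoint(0.799, 0.892, 0.30)),
        _stratum("ULH", "Siemens", "UK", 58800 / 275900,
                 OperatingPoint(0.767, 0.964, 0.07),
                 OperatingPoint(0.773, 0.899, 0.30)),
    ]


#: Age bands (low, high, count weight) matching the ten-year cohort mix.
DEFAULT_AGE_BANDS: tuple[tuple[int, int, int], ...] = (
    (35, 39, 483), (40, 49, 37696), (50, 59, 114524), (60, 69, 98289),
    (70, 79, 23359), (80, 89, 1534), (90, 95, 15),
)


@dataclass(frozen=True)
class SynthParams:
    """Full generative specification of a synthetic cohort."""

    n_cases: int = 10_000
    strata: tuple[StratumSpec, ...] = tuple(default_strata())
    age_bands: tuple[tuple[int, int, int], ...] = DEFAULT_AGE_BANDS
    p_screen_detected: float = 0.0084
    p_interval_cancer: float = 0.0014
    p_negative_followup: float = 0.30
    unconfirmed_recall_factor: float = 1.5
    rho_hh: float = 0.80
    rho_ha: float = 0.25
    arbitrate_agreed_recalls: bool = False
    repeat_attendance_fraction: float = 0.0
    date_start: dt.date = dt.date(2009, 1, 1)
    date_end: dt.date = dt.date(2018, 12, 31)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(s.proportion for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"stratum proportions sum to {total}, not 1")
        for p in (self.p_screen_detected, self.p_interval_cancer,
                  self.p_negative_followup, self.repeat_attendance_fraction):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0, 1]")
        if self.p_screen_detected + self.p_interval_cancer >= 1.0:
            raise ParameterError("cancer prevalence components must sum below 1")
        for rho in (self.rho_hh, self.rho_ha):
            if not 0.0 <= rho < 1.0:
                raise ParameterError(f"correlation {rho} outside [0, 1)")
        if self.unconfirmed_recall_factor < 0:
            raise ParameterError("unconfirmed_recall_factor must be >= 0")
        _correlation_matrix(self.rho_hh, self.rho_ha)  # PSD check


def _correlation_matrix(rho_hh: float, rho_ha: float) -> np.ndarray:
    m = np.array([
        [1.0, rho_hh, rho_hh, rho_ha],
        [rho_hh, 1.0, rho_hh, rho_ha],
        [rho_hh, rho_hh, 1.0, rho_ha],
        [rho_ha, rho_ha, rho_ha, 1.0],
    ])
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ParameterError(
            f"correlation structure rho_hh={rho_hh}, rho_ha={rho_ha} is not "
            "positive semidefinite")
    return m


def _recall_probability(op: OperatingPoint, disease_class: str,
                        followed: bool, factor: float) -> float:
    if disease_class == SD_CANCER:
        return op.sens
    if disease_class == IC_CANCER:
        return op.ic_hit
    fp = 1.0 - op.spec
    return fp if followed else min(1.0, factor * fp)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    params: SynthParams,
    return_truth: bool = False,
):
    """Generate a cohort of :class:`CaseRecord`, deterministic per seed.

    With ``return_truth`` a second value is returned: a list of dicts with
    each case's latent class and intended ground-truth category (omniscient
    truth, unavailable in real retrospective data).
    """
    n = params.n_cases
    rng = np.random.default_rng(params.rng_seed)
    strata = list(params.strata)

    s_idx = rng.choice(len(strata), size=n, p=[s.proportion for s in strata])
    class_p = [params.p_screen_detected, params.p_interval_cancer,
               1.0 - params.p_screen_detected - params.p_interval_cancer]
    c_idx = rng.choice(3, size=n, p=class_p)  # 0=SD, 1=IC, 2=free
    followed = (c_idx == 2) & (rng.random(n) < params.p_negative_followup)

    bands = np.asarray([(lo, hi) for lo, hi, _ in params.age_bands])
    weights = np.asarray([w for *_, w in params.age_bands], dtype=float)
    b_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    ages = rng.integers(bands[b_idx, 0], bands[b_idx, 1] + 1)

    span = (params.date_end - params.date_start).days + 1
    date_offsets = rng.integers(0, span, size=n)

    # Correlated latent scores -> opinions.
    corr = _correlation_matrix(params.rho_hh, params.rho_ha)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    z = rng.standard_normal((n, 4)) @ chol.T

    classes = np.array([SD_CANCER, IC_CANCER, CANCER_FREE])[c_idx]
    p = np.empty((n, 4))
    for si, spec in enumerate(strata):
        for ci, cls in enumerate((SD_CANCER, IC_CANCER, CANCER_FREE)):
            for fl in (False, True):
                mask = (s_idx == si) & (c_idx == ci) & (followed == fl)
                if not mask.any():
                    continue
                for ri, reader in enumerate(READERS):
                    p[mask, ri] = _recall_probability(
                        spec.op(reader), cls, fl, params.unconfirmed_recall_factor)
    recall = z < ndtri(np.clip(p, 0.0, 1.0))
    r1, r2, arb_opinion, ai = recall.T

    # Historical workflow replay determines which cases were arbitrated and
    # the recorded final decision.
    disagree = r1 != r2
    if params.arbitrate_agreed_recalls:
        need_arb = disagree | (r1 & r2)
    else:
        need_arb = disagree
    final = np.where(need_arb, arb_opinion, r1)

    # Outcome events, generated from the intended label.
    sd_detected = (c_idx == 0) & final
    path_offset_sd = rng.integers(7, 181, size=n)
    windows = np.array([1095 if s.region == "UK" else 730 for s in strata])
    path_offset_ic = 181 + (rng.random(n) *
                            (windows[s_idx] - 180)).astype(int)  # in [181, window]
    fu_offset = rng.integers(1035, 1151, size=n)

    # Participant assignment: one case per participant, except a configurable
    # repeat-attendance fraction that reuses the previous participant.
    repeat = rng.random(n) < params.repeat_attendance_fraction
    repeat[0] = False

    cases: list[CaseRecord] = []
    truth: list[dict] = []
    pid = -1
    for i in range(n):
        if not repeat[i]:
            pid += 1
        spec = strata[s_idx[i]]
        screening = params.date_start + dt.timedelta(days=int(date_offsets[i]))
        case = CaseRecord(
            case_id=f"C{i:07d}",
            participant_id=f"P{pid:07d}",
            site=spec.site, vendor=spec.vendor, region=spec.region,
            screening_date=screening,
            age_years=int(ages[i]),
            r1=RECALL if r1[i] else NO_RECALL,
            r2=RECALL if r2[i] else NO_RECALL,
            arbitration=(RECALL if arb_opinion[i] else NO_RECALL) if need_arb[i] else None,
            historical_final=RECALL if final[i] else NO_RECALL,
            ai=RECALL if ai[i] else NO_RECALL,
        )
        intended = "unconfirmed"
        if c_idx[i] == 0 and final[i]:
            case.pathology_events.append(PathologyEvent(
                screening + dt.timedelta(days=int(path_offset_sd[i])),
                malignant=True, proven_by="histology"))
            intended = "screen_detected_positive"
        elif c_idx[i] == 1:
            case.pathology_events.append(PathologyEvent(
                screening + dt.timedelta(days=int(path_offset_ic[i])),
                malignant=True, proven_by="histology"))
            intended = "interval_cancer"
        elif c_idx[i] == 2 and followed[i]:
            case.followup_mammograms.append(
                screening + dt.timedelta(days=int(fu_offset[i])))
            intended = "confirmed_negative"
        cases.append(case)
        if return_truth:
            truth.append({"case_id": case.case_id, "latent_class": classes[i],
                          "intended_category": intended})
    if return_truth:
        return cases, truth
    return cases


def params_from_dict(cfg: dict) -> SynthParams:
    """Build :class:`SynthParams` from a parsed declarative config.

    Unspecified fields keep their defaults; strata may be given as a list of
    mappings with per-reader ``{sens, spec, ic_hit}`` operating points.
    """
    kwargs: dict = {}
    simple = ("n_cases", "p_screen_detected", "p_interval_cancer",
              "p_negative_followup", "unconfirmed_recall_factor", "rho_hh",
              "rho_ha", "arbitrate_agreed_recalls",
              "repeat_attendance_fraction", "rng_seed")
    for key in simple:
        if key in cfg:
            kwargs[key] = cfg[key]
    for key in ("date_start", "date_end"):
        if key in cfg:
            kwargs[key] = dt.date.fromisoformat(str(cfg[key]))
    if "strata" in cfg:
        strata = []
        for s in cfg["strata"]:
            ops = {r: OperatingPoint(**s[r]) for r in READERS}
            strata.append(StratumSpec(
                site=s["site"], vendor=s["vendor"], region=s["region"],
                proportion=float(s["proportion"]),
                r1=ops["r1"], r2=ops["r2"], arb=ops["arb"], ai=ops["ai"]))
        kwargs["strata"] = tuple(strata)
    if "age_bands" in cfg:
        kwargs["age_bands"] = tuple(
            (int(lo), int(hi), int(w)) for lo, hi, w in cfg["age_bands"])
    return SynthParams(**kwargs)


# ---------------------------------------------------------------------------
# Closed-form disagreement and arbitration-rate calibration
# ---------------------------------------------------------------------------

def _bvn_both_below(ta: float, tb: float, rho: float) -> float:
    """P(Za <= ta, Zb <= tb) for standard bivariate normal with corr rho."""
    if np.isneginf(ta) or np.isneginf(tb):
        return 0.0
    if np.isposinf(ta):
        return float(multivariate_normal(cov=1.0).cdf(tb)) if not np.isposinf(tb) else 1.0
    if np.isposinf(tb):
        return float(multivariate_normal(cov=1.0).cdf(ta))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(multivariate_normal(mean=[0, 0], cov=cov).cdf([ta, tb]))


def _class_mixture(params: SynthParams):
    """(class, followed, weight) components of the disease-class mixture."""
    p_free = 1.0 - params.p_screen_detected - params.p_interval_cancer
    return [
        (SD_CANCER, False, params.p_screen_detected),
        (IC_CANCER, False, params.p_interval_cancer),
        (CANCER_FREE, True, p_free * params.p_negative_followup),
        (CANCER_FREE, False, p_free * (1.0 - params.p_negative_followup)),
    ]


def expected_disagreement(
    params: SynthParams, pair: tuple[str, str], rho: float,
) -> float:
    """Exact probability that two readers disagree under the copula model.

    Mixes P(disagree) = p_a + p_b - 2 P(both recall) over strata and disease
    classes, with P(both recall) a bivariate-normal orthant probability.
    """
    total = 0.0
    for spec in params.strata:
        for cls, fl, w in _class_mixture(params):
            pa = _recall_probability(spec.op(pair[0]), cls, fl,
                                     params.unconfirmed_recall_factor)
            pb = _recall_probability(spec.op(pair[1]), cls, fl,
                                     params.unconfirmed_recall_factor)
            both = _bvn_both_below(ndtri(pa), ndtri(pb), rho)
            total += spec.proportion * w * (pa + pb - 2.0 * both)
    return total


def simulate_disagreement(
    params: SynthParams, n: int, seed: int,
) -> dict[str, float]:
    """Monte-Carlo disagreement rates (opinions only, no case assembly)."""
    rng = np.random.default_rng(seed)
    strata = list(params.strata)
    s_idx = rng.choice(len(strata), size=n, p=[s.proportion for s in strata])
    class_p = [params.p_screen_detected, params.p_interval_cancer,
               1.0 - params.p_screen_detected - params.p_interval_cancer]
    c_idx = rng.choice(3, size=n, p=class_p)
    followed = (c_idx == 2) & (rng.random(n) < params.p_negative_followup)
    corr = _correlation_matrix(params.rho_hh, params.rho_ha)
    z = rng.standard_normal((n, 4)) @ np.linalg.cholesky(corr + 1e-12 * np.eye(4)).T
    p = np.empty((n, 4))
    for si, spec in enumerate(strata):
        for ci, cls in enumerate((SD_CANCER, IC_CANCER, CANCER_FREE)):
            for fl in (False, True):
                mask = (s_idx == si) & (c_idx == ci) & (followed == fl)
                if not mask.any():
                    continue
                for ri, reader in enumerate(READERS):
                    p[mask, ri] = _recall_probability(
                        spec.op(reader), cls, fl, params.unconfirmed_recall_factor)
    recall = z < ndtri(np.clip(p, 0.0, 1.0))
    return {
        "human_human": float((recall[:, 0] != recall[:, 1]).mean()),
        "human_ai": float((recall[:, 0] != recall[:, 3]).mean()),
    }


def _bisect_rho(params: SynthParams, pair: tuple[str, str],
                target: float, tol: float) -> float:
    lo, hi = 0.0, 0.999
    d_lo = expected_disagreement(params, pair, lo)   # max disagreement
    d_hi = expected_disagreement(params, pair, hi)   # min disagreement
    if not (d_hi - 1e-12 <= target <= d_lo + 1e-12):
        raise ParameterError(
            f"target disagreement {target:.4f} for pair {pair} unreachable: "
            f"achievable range is [{d_hi:.4f}, {d_lo:.4f}] for rho in [0, 1)")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        d = expected_disagreement(params, pair, mid)
        if abs(d - target) < tol / 10.0:
            return mid
        if d > target:   # too much disagreement -> increase correlation
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_arbitration_rate(
    params: SynthParams,
    target_hist: float = 0.033,
    target_ai: float = 0.123,
    tol: float = 0.002,
    n_check: int = 1_000_000,
) -> tuple[SynthParams, dict[str, float]]:
    """Tune the copula correlations so simulated disagreement rates hit the
    published arbitration rates (human double reading vs double reading with
    AI).

    ``rho_hh`` is bisected against the closed-form expected human-human
    disagreement and ``rho_ha`` against the human-AI one; the result is then
    verified by simulation at ``n_check`` cases, which must match the targets
    within ``tol`` (default 0.2 percentage points).

    Returns the updated params and the achieved (simulated) rates.
    """
    for t in (target_hist, target_ai):
        if not 0.0 < t < 1.0:
            raise ParameterError(f"target rate {t} outside (0, 1)")
    rho_hh = _bisect_rho(params, ("r1", "r2"), target_hist, tol)
    rho_ha = _bisect_rho(params, ("r1", "ai"), target_ai, tol)
    new = replace(params, rho_hh=rho_hh, rho_ha=rho_ha)  # re-runs PSD check
    achieved = simulate_disagreement(new, n_check, new.rng_seed)
    if (abs(achieved["human_human"] - target_hist) > tol
            or abs(achieved["human_ai"] - target_ai) > tol):
        raise ParameterError(
            f"calibration check failed: achieved {achieved} vs targets "
            f"({target_hist}, {target_ai}) at tolerance {tol}")
    return new, achieved
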