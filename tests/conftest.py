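import datetime as dt

import pytest

from dualread import (CaseRecord, SynthParams, default_site_configs,
                      generate_cohort)


@pytest.fixture(scope="session")
def site_configs():
    return default_site_configs()


def make_case(
    case_id="C1",
    participant_id=None,
    site="LTHT",
    vendor="Hologic",
    region="UK",
    screening_date=dt.date(2015, 6, 1),
    age_years=55,
    r1="no_recall",
    r2="no_recall",
    arbitration=None,
    historical_final=None,
    ai="no_recall",
    n_views=4,
    pathology_events=(),
    followup_mammograms=(),
):
    """Hand-built screening case with sensible defaults."""
    if historical_final is None:
        # Default to the plain fused outcome so records are self-consistent.
        if r1 == r2:
            historical_final = r1
        elif arbitration is not None:
            historical_final = arbitration
        else:
            historical_final = "no_recall"
    case = CaseRecord(
        case_id=case_id,
        participant_id=participant_id or f"P-{case_id}",
        site=site, vendor=vendor, region=region,
        screening_date=screening_date, age_years=age_years,
        r1=r1, r2=r2, arbitration=arbitration,
        historical_final=historical_final, ai=ai, n_views=n_views,
        pathology_events=list(pathology_events),
        followup_mammograms=list(followup_mammograms),
    )
    return case


@pytest.fixture(scope="session")
def small_cohort():
    """A 20,000-case synthetic cohort with its omniscient truth, shared
    across tests that only need a realistic mid-sized cohort."""
    params = SynthParams(n_cases=20_000, rng_seed=20240501)
    cases, truth = generate_cohort(params, return_truth=True)
    return params, cases, truth
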