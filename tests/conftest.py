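import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exaflare as ex

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def shape_cohort() -> ex.SimulatedCohort:
    """Small shape-mode cohort: scheduled episodes with the stereotyped course."""
    params = ex.CohortParams(n_patients=60, followup_days=180)
    return ex.simulate_cohort(params, seed=42)


@pytest.fixture(scope="session")
def hazard_cohort() -> ex.SimulatedCohort:
    """Hazard-mode cohort: onsets driven by the window score (beta_true=0.5)."""
    params = ex.CohortParams(
        mode="hazard", n_patients=150, followup_days=250, beta_true=0.5
    )
    return ex.simulate_cohort(params, seed=7)


@pytest.fixture(scope="session")
def counting_table(hazard_cohort) -> pd.DataFrame:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ex.build_counting_process(hazard_cohort.diary, hazard_cohort.episodes)


def make_diary(rows: list[dict]) -> pd.DataFrame:
    """Build a diary frame from sparse row dicts (missing fields -> NaN)."""
    base = {c: np.nan for c in ex.diary_model.DIARY_COLUMNS}
    return pd.DataFrame([{**base, **r} for r in rows])


def complete_diary(
    patient_id: str,
    days,
    dyspnea=1,
    cough=1,
    sputum=1,
    nocturnal=0,
    pef=300.0,
    salbutamol=1.0,
) -> pd.DataFrame:
    """Constant, fully scored diary over the given days."""
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "day": list(days),
            "dyspnea": dyspnea,
            "cough": cough,
            "sputum": sputum,
            "nocturnal": nocturnal,
            "pef1": pef,
            "pef2": pef - 5.0,
            "pef3": pef - 10.0,
            "salbutamol": salbutamol,
        }
    )
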