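import datetime as dt

import pytest

from ctpirp.cohort import PatientRecord

SEED = 1  # suite-wide base seed


def make_patient(
    patient_id="P1",
    center_id=1,
    cohort="derivation",
    sex="male",
    age=65.0,
    diabetes=False,
    egfr_baseline=30.0,
    enrol="2005-01-01",
    exit="2008-01-01",
    outcome="admin_censor",
    **kwargs,
):
    """Minimal valid patient; covariates overridable per test."""
    return PatientRecord(
        patient_id=patient_id,
        center_id=center_id,
        cohort=cohort,
        sex=sex,
        age=age,
        diabetes=diabetes,
        egfr_baseline=egfr_baseline,
        enrol_date=dt.date.fromisoformat(enrol),
        exit_date=dt.date.fromisoformat(exit),
        outcome=outcome,
        **kwargs,
    )


# Published per-node mean covariate profiles of the derivation cohort
# (age, baseline eGFR, phosphate, diabetes share, male share).
TABLE1_PROFILES = {
    1: dict(proteinuria=True, egfr_baseline=46.7, phosphate=3.60, age=63.8, diabetes=True, sex="male"),
    2: dict(proteinuria=True, egfr_baseline=23.2, phosphate=3.62, age=70.3, diabetes=False, sex="male"),
    3: dict(proteinuria=True, egfr_baseline=18.9, phosphate=5.10, age=65.7, diabetes=True, sex="female"),
    4: dict(proteinuria=False, egfr_baseline=34.0, phosphate=3.80, age=54.9, diabetes=False, sex="male"),
    5: dict(proteinuria=False, egfr_baseline=31.9, phosphate=3.99, age=61.1, diabetes=True, sex="male"),
    6: dict(proteinuria=False, egfr_baseline=24.5, phosphate=4.03, age=78.6, diabetes=False, sex="female"),
    7: dict(proteinuria=False, egfr_baseline=28.9, phosphate=3.59, age=78.2, diabetes=False, sex="male"),
}


@pytest.fixture
def table1_patients():
    return [
        make_patient(patient_id=f"T{node}", **profile)
        for node, profile in TABLE1_PROFILES.items()
    ]


@pytest.fixture(scope="session")
def small_cohorts():
    """One derivation + one validation synthetic cohort, shared across tests."""
    from ctpirp.simulate import SimulationConfig, generate_cohort

    d, truth = generate_cohort(
        SimulationConfig(n_patients=1500, cohort="derivation"), seed=SEED
    )
    v, _ = generate_cohort(
        SimulationConfig(n_patients=1500, cohort="validation"), seed=SEED + 1
    )
    return d, v, truth
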