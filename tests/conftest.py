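import numpy as np
import pytest

from neurocohort.risk import ClinicalRecord
from neurocohort.synthetic import generate_cohort


def make_record(**overrides) -> ClinicalRecord:
    """A clinically healthy subject; override fields to flip risk clauses."""
    base = dict(
        subject_id="S1",
        age=60.0,
        gender="female",
        sbp=120.0,
        dbp=75.0,
        glycemia=0.95,
        cholesterol=2.0,
        bmi=24.0,
        active_smoker=False,
        self_reported_diabetes=False,
        antidiabetic_drug=False,
        self_reported_hypertension=False,
        antihypertensive_drug=False,
        self_reported_hypercholesterolemia=False,
        lipid_lowering_drug=False,
        gds=3.0,
        high_education=True,
    )
    base.update(overrides)
    return ClinicalRecord(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort shared across tests (n = 150)."""
    return generate_cohort(seed=42, n_subjects=150)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
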