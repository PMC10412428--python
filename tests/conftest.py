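import numpy as np
import pandas as pd
import pytest

from nashtriage import GeneratorConfig, generate_cohort
from nashtriage.cohort import PatientRecord


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One seeded default-condition cohort shared across tests."""
    return generate_cohort(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def ge65_cohort() -> pd.DataFrame:
    """Seeded cohort restricted to the >=65 stratum (n = 410)."""
    return generate_cohort(GeneratorConfig().ge65_only(410), seed=11)


@pytest.fixture()
def complete_record() -> PatientRecord:
    return PatientRecord(
        patient_id="P1", age=60, sex="female", fibrosis_stage=2, nas=5,
        gap_days=10, diabetes=False, bmi=31.0, ast=40.0, alt=40.0,
        platelets=200.0, albumin=4.0, mir34a=1.5, ykl40=90.0, a2m=2.1,
        hba1c=6.0, ha=50.0, piiinp=9.0, timp1=250.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
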