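import numpy as np
import pandas as pd
import pytest

from ldltraj.ehr_model import CohortConfig, validate_tables
from ldltraj.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def config():
    return CohortConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort shared across tests (seeded)."""
    cfg = GeneratorConfig(n_patients=400, seed=11)
    tables, truth = generate_cohort(cfg)
    return validate_tables(tables), truth


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture
def labs_frame():
    """Hand-built labs table covering direct, derivable and incomplete dates."""
    rows = [
        ("A", "2010-01-05", "TC", 5.0),
        ("A", "2010-01-05", "HDL", 1.0),
        ("A", "2010-01-05", "TG", 2.2),
        ("B", "2010-02-01", "LDL_direct", 2.0),
        ("B", "2010-02-01", "TC", 4.5),
        ("B", "2010-02-01", "HDL", 1.1),
        ("B", "2010-02-01", "TG", 1.8),
        ("C", "2010-03-01", "TC", 4.0),  # incomplete: no panel
        ("C", "2010-03-01", "HDL", 1.0),
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "date", "analyte", "value"])
    df["date"] = pd.to_datetime(df["date"])
    return df
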