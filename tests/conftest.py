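import numpy as np
import pandas as pd
import pytest

from gccscreen import default_config, generate_cohort
from gccscreen.cohort import BIOMARKERS, CohortTable


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject synthetic cohort with its latent truth (no missing)."""
    cohort, truth = generate_cohort(default_config(n=300, seed=7))
    return cohort, truth


@pytest.fixture()
def table1_row():
    """One subject sitting exactly at the published total biomarker means."""
    row = {
        "subject_id": "S0", "age": 55.0,
        "bmi": 22.54, "whr": 0.86, "tc": 4.46, "tg": 1.73, "hdl": 1.30,
        "ldl": 2.75, "fpg": 4.88, "ogtt2h": 6.50, "sbp": 120.39, "dbp": 76.50,
        "menarche_age": 14.0, "menopause_age": 49.0, "repro_lifespan": 35.0,
        "live_births": 1.0, "abortions": 0.0,
    }
    return CohortTable(pd.DataFrame([row]))


def make_cohort_frame(n, rng, **overrides):
    """Minimal complete cohort frame with standard-normal-ish biomarkers."""
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "age": rng.uniform(41, 80, n).round(1),
    })
    for b in BIOMARKERS:
        df[b] = rng.normal(5.0, 1.0, n)
    men = rng.uniform(12, 17, n)
    menop = rng.uniform(45, 52, n)
    df["menarche_age"] = men
    df["menopause_age"] = menop
    df["repro_lifespan"] = menop - men
    df["live_births"] = rng.integers(0, 4, n).astype(float)
    df["abortions"] = rng.integers(0, 3, n).astype(float)
    for col, vals in overrides.items():
        df[col] = vals
    return df
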