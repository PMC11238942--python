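import numpy as np
import pandas as pd
import pytest

import mmsetraj as mt


@pytest.fixture(scope="session")
def mci_table():
    return mt.load_published_coefficients("MCI")


@pytest.fixture(scope="session")
def dem_table():
    return mt.load_published_coefficients("mild_dementia")


@pytest.fixture
def median_mci_patient():
    """Hypothetical median MCI patient: male, 66 y, log pTau 3.415,
    Abeta1-42 796.22 pg/mL, baseline MMSE 27."""
    return mt.PatientProfile(
        "MCI", {"age": 66, "sex": 1, "mmse_bl": 27, "log_ptau": 3.415, "abeta42": 796.22}
    )


@pytest.fixture
def prognosis_mci_patient():
    """MCI prognosis example: baseline MMSE 28, Abeta1-42 925 pg/mL."""
    return mt.PatientProfile(
        "MCI", {"age": 66, "sex": 1, "mmse_bl": 28, "log_ptau": 3.415, "abeta42": 925.0}
    )


@pytest.fixture
def prognosis_dem_patient():
    """Mild-dementia prognosis example: female, 2 APOE e4 alleles,
    baseline MMSE 20, Abeta1-42 625 pg/mL."""
    return mt.PatientProfile(
        "mild_dementia",
        {"age": 66, "sex": 0, "apoe4": 2, "mmse_bl": 20, "log_ptau": 3.498, "abeta42": 625.0},
    )


@pytest.fixture(scope="session")
def small_complete_cohort():
    """120 MCI subjects, no covariate missingness (fast fitting fixture)."""
    cfg = mt.CohortConfig(n_subjects=120, group="MCI", seed=11)
    return mt.generate_cohort(cfg, with_missingness=False)


@pytest.fixture(scope="session")
def small_missing_cohort():
    """150 MCI subjects with default covariate missingness."""
    cfg = mt.CohortConfig(n_subjects=150, group="MCI", seed=12)
    return mt.generate_cohort(cfg)


@pytest.fixture(scope="session")
def completed_sets(small_missing_cohort):
    """Three chained-equation completions of the missing-data cohort."""
    conf = mt.ImputationConfig(m=3, n_iterations=4, seed=5)
    return mt.mice_impute(small_missing_cohort, conf)


def true_structure_terms():
    """ModelTerm list matching the published MCI biomarker model structure."""
    return (
        mt.ModelTerm("age", role="both", forced=True),
        mt.ModelTerm("sex", role="both", forced=True),
        mt.ModelTerm("mmse_bl", role="constant"),
        mt.ModelTerm("ptau", transform="log", role="both"),
        mt.ModelTerm("abeta42", role="both"),
    )
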