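import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import metadrift as md

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table():
    """Hand-built 3-feature x 5-injection table with one QC pair and a blank."""
    features = pd.DataFrame(
        {
            "mz_med": [90.0556, 212.0013, 300.1234],
            "rt_med": [12.2, 9.13, 5.0],
            "ion_mode": ["positive", "negative", "positive"],
        },
        index=pd.Index(["F1", "F2", "F3"], name="feature_id"),
    )
    intensities = pd.DataFrame(
        [
            [100.0, 110.0, 1.0, 105.0, 120.0],
            [50.0, 55.0, 40.0, 52.0, 60.0],
            [10.0, np.nan, 0.5, 11.0, 9.0],
        ],
        index=features.index,
        columns=["Q001", "Q002", "B001", "S001", "S002"],
    )
    injections = pd.DataFrame(
        {
            "order": [1, 2, 3, 4, 5],
            "sample_type": ["qc", "qc", "blank", "serum", "serum"],
            "patient_id": [None, None, None, "P01", "P01"],
            "timepoint": [None, None, None, "PRE", "POST"],
        },
        index=pd.Index(["Q001", "Q002", "B001", "S001", "S002"], name="injection_id"),
    )
    patients = pd.DataFrame(
        {
            "center": ["A"],
            "weight_pre": [126.4],
            "weight_fu": [86.3],
            "diabetic_at_baseline": [True],
            "remission": [True],
            "hba1c_pre": [7.1],
            "hba1c_fu": [5.9],
        },
        index=pd.Index(["P01"], name="patient_id"),
    )
    return md.FeatureTable(features, intensities), md.StudyDesign(injections, patients)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated study (44 patients, 923 features)."""
    return md.simulate(md.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def corrected_sim(default_sim):
    """Default simulation after blank/detection filtering and drift correction."""
    table, design, truth = default_sim
    filtered = md.apply_filters(
        table, md.blank_filter(table, design), md.detection_filter(table, design)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, report, models = md.correct_table(filtered, design)
    return corrected, design, truth, report, models
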