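import numpy as np
import pandas as pd
import pytest

from invigor import GeneratorConfig, cohort_from_frame, generate_cohort


def toy_cohort_frame():
    """Five hand-written patients exercising all canonical columns."""
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4", "P5"],
            "screen_dim_major": [12.0, 15.0, 10.0, 9.0, 20.0],
            "screen_dim_minor": [8.0, 10.0, 10.0, 6.0, 12.0],
            "diag_dim_major": [18.0, 22.0, 10.0, 14.0, 28.0],
            "diag_dim_minor": [12.0, 15.0, 10.0, 9.0, 18.0],
            "interval_days": [400.0, 500.0, 365.0, 600.0, 550.0],
            "age_years": [55.0, 62.0, 58.0, 66.0, 51.0],
            "grade": [2.0, 3.0, 1.0, 2.0, 3.0],
            "histological_size_mm": [18.0, 25.0, 9.0, 15.0, 30.0],
            "npi": [3.36, 4.5, 2.18, 3.3, 5.6],
            "mitotic_score": [2.0, 3.0, 1.0, 1.0, 3.0],
            "nodal_stage": [1.0, 1.0, 1.0, 2.0, 2.0],
            "ki67_percent": [12.0, 35.0, np.nan, 8.0, 40.0],
            "er_status": ["positive", "negative", "positive", "positive", "negative"],
            "pr_status": ["positive", "negative", "positive", "negative", "negative"],
            "her2_status": ["negative", "positive", np.nan, "negative", "negative"],
            "lvi": ["negative", "definite", "negative", "probable", "definite"],
            "subtype": ["luminal A", "TNBC", "luminal A", "luminal B", np.nan],
            "bcss_months": [130.0, 24.0, 150.0, 96.0, 40.0],
            "event": [0.0, 1.0, 0.0, 0.0, 1.0],
        }
    )


@pytest.fixture
def toy_cohort():
    return cohort_from_frame(toy_cohort_frame(), provenance="toy")


@pytest.fixture
def synthetic_cohort_small():
    cohort, truth = generate_cohort(GeneratorConfig(n=92, seed=7))
    return cohort, truth
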