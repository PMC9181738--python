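import numpy as np
import pandas as pd
import pytest

from dualbench.benchmarking import BootstrapConfig, benchmark_centers
from dualbench.pipeline import apply_all_filters, outcome_to_binary
from dualbench.study import develop_dual_models, prepare_model_frame
from dualbench.synthetic import SyntheticConfig, generate_cohort


def clean_config(**kw) -> SyntheticConfig:
    """A generator config with all messiness rates off (analysis-ready)."""
    defaults = dict(readmission_rate=0.0, incomplete_month_rate=0.0,
                    background_incomplete_rate=0.0, missing_outcome_rate=0.0,
                    pediatric_rate=0.0, typeb_rate=0.0, icu_before_rate=0.0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def dev_cohort():
    """A mid-size messy cohort with one genuinely deviant center (C03)."""
    cfg = SyntheticConfig(n_centers=12, patients_per_center=500, seed=11,
                          center_intraop_shift={"C03": 0.3})
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def dev_models(dev_cohort):
    """Paired models developed on the filtered dev cohort."""
    _, cohort, truth = dev_cohort
    analysed, report = apply_all_filters(cohort)
    analysed = prepare_model_frame(analysed).reset_index(drop=True)
    y = outcome_to_binary(analysed)
    pre, pre_rep, post, post_rep = develop_dual_models(analysed, y)
    return {"cohort": analysed, "y": y, "pre": pre, "post": post,
            "pre_report": pre_rep, "post_report": post_rep,
            "filter_report": report, "truth": truth}


@pytest.fixture(scope="session")
def dev_benchmarks(dev_models):
    bms = benchmark_centers(dev_models["cohort"], dev_models["pre"],
                            dev_models["post"],
                            boot=BootstrapConfig(B=100, seed=5))
    return bms


@pytest.fixture
def toy_cohort():
    """Five records incl. one re-admission, a minor and a Type-B repair."""
    return pd.DataFrame({
        "patient_id": ["p1", "p2", "p2", "p3", "p4"],
        "center_id": ["C01"] * 5,
        "age": [70.0, 55.0, 55.0, 16.0, 80.0],
        "readmission_index": [1, 1, 2, 1, 1],
        "typeB_dissection_repair": [0, 0, 0, 0, 0],
        "admitted_to_icu_before_surgery": [0, 0, 0, 0, 0],
        "admission_year": [2016] * 5,
        "admission_month": [1, 1, 2, 2, 3],
        "complete": [1, 1, 1, 1, 1],
        "hospital_outcome": ["alive", "alive", "alive", "dead", "missing"],
    })
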