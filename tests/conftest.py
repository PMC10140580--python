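import numpy as np
import pandas as pd
import pytest

from vacpred import MissingnessPolicy, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort with no missingness/outliers and ground truth."""
    cfg = SimConfig(
        n_patients=30, seed=7, missing_rate=0.0, outlier_rate=0.0,
        vent_duration_hours=(96, 200),
    )
    return generate_cohort(cfg)


@pytest.fixture()
def policy():
    means = {
        name: float(m)
        for name, m in {
            "HR": 85, "RR": 18, "SBP": 120, "DBP": 65, "MAP": 83,
            "SpO2": 96, "TEMP": 37, "airway_pressure": 15, "pH": 7.38,
            "PaO2": 95, "glucose": 130, "WBC": 10, "GCS": 9,
            "PEEP": 5, "FiO2": 40,
        }.items()
    }
    return MissingnessPolicy(training_means=means)


@pytest.fixture()
def hourly_series():
    """Hourly-charted series factory on a fixed ventilation clock."""
    start = pd.Timestamp("2021-03-01 00:00")

    def make(values, interval_hours=1.0, offset=0.0):
        values = np.asarray(values, dtype=float)
        idx = start + pd.to_timedelta(
            offset + np.arange(len(values)) * interval_hours, unit="h"
        )
        return pd.Series(values, index=idx)

    make.start = start
    return make
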