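"""Shared fixtures: a small simulated cohort reused across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wardsense import (CohortConfig, SensorStream, build_dataset,
                       featurize_cohort, generate_cohort)


@pytest.fixture(scope="session")
def tiny_config() -> CohortConfig:
    return CohortConfig(n_participants=6, seed=3, stay_mean_days=10,
                        stay_sd_days=3, stay_min_days=8, stay_max_days=14)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    series, log = featurize_cohort(tiny_cohort)
    return series, log


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort, tiny_features):
    series, _ = tiny_features
    return build_dataset(tiny_cohort, series)


def constant_stream(n_hours: int = 48, hr: float = 70.0,
                    accel=(0.0, 0.0, 1.0), zone: str = "room",
                    loc=(1.0, 2.0), steps: float = 1.0,
                    participant_id: str = "pX") -> SensorStream:
    """Minute-cadence stream with every channel constant."""
    n = n_hours * 60
    ts = pd.date_range("2024-01-01 00:00", periods=n, freq="1min")
    df = pd.DataFrame({
        "timestamp": ts,
        "heart_rate": np.full(n, hr),
        "accel_x": np.full(n, accel[0]),
        "accel_y": np.full(n, accel[1]),
        "accel_z": np.full(n, accel[2]),
        "loc_x": np.full(n, loc[0]),
        "loc_y": np.full(n, loc[1]),
        "zone": np.full(n, zone, dtype=object),
        "calories": np.full(n, 1.1),
        "steps": np.full(n, steps),
        "distance": np.full(n, steps * 0.7),
        "sleep_flag": np.zeros(n),
    })
    return SensorStream(participant_id, df)
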