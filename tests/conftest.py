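import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nursevam import (
    SimulationConfig,
    apply_exclusions,
    label_outcomes,
    simulate_extract,
    split_sample,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_run():
    """One full-scale (study-sized) simulated year, assembled and split.

    Shared across test modules to keep the suite fast; tests must not
    mutate it.
    """
    cfg = SimulationConfig(seed=11)
    extract, effects = simulate_extract(cfg)
    encounters = label_outcomes(extract)
    cohort = apply_exclusions(
        encounters, extract.event_table, float_nurses=extract.float_nurses
    )
    est, val = split_sample(cohort, "2016-01-01")
    return {
        "config": cfg,
        "extract": extract,
        "effects": effects,
        "cohort": cohort,
        "est": est,
        "val": val,
    }


@pytest.fixture(scope="session")
def small_run():
    """A small two-unit year (10 nurses) for cheaper model-level tests."""
    cfg = SimulationConfig(
        seed=7,
        n_nurses_per_unit={"medical": 5, "neurological": 5},
        n_beds_per_unit={"medical": 5, "neurological": 5},
    )
    extract, effects = simulate_extract(cfg)
    encounters = label_outcomes(extract)
    cohort = apply_exclusions(
        encounters, extract.event_table, float_nurses=extract.float_nurses
    )
    est, val = split_sample(cohort, "2016-01-01")
    return {
        "config": cfg,
        "extract": extract,
        "effects": effects,
        "cohort": cohort,
        "est": est,
        "val": val,
    }


def make_toy_extract(event_offsets_h, n_shifts=6, admit_minute=30):
    """Single-patient extract with ``n_shifts`` consecutive 12 h shifts.

    ``event_offsets_h`` are confirmed-CAABU timestamps given in hours after
    the FIRST shift's start.  Used for attribution-window arithmetic tests.
    """
    from nursevam.simulate import RawEhrExtract

    t0 = pd.Timestamp("2015-07-02 07:00")  # a day shift start
    admit = t0 - pd.Timedelta(minutes=admit_minute)
    rows = []
    for s in range(n_shifts):
        start = t0 + pd.Timedelta(hours=12 * s)
        rows.append(
            {
                "patient_id": "P1",
                "nurse_id": f"N{s % 2 + 1:03d}",
                "shift_date": start.normalize(),
                "shift_kind": "day" if start.hour == 7 else "night",
            }
        )
    patients = pd.DataFrame(
        [
            {
                "patient_id": "P1",
                "age": 60.0,
                "sex": "male",
                "mdc": "DDs of Nervous System",
                "insurance": "private",
                "admission_type": "medical",
                "prior_admission_30d": 0,
                "unit": "medical",
                "icu_admit_time": admit,
                "icu_discharge_time": t0 + pd.Timedelta(hours=12 * n_shifts),
            }
        ]
    )
    events = pd.DataFrame(
        [
            {
                "patient_id": "P1",
                "event_time": t0 + pd.Timedelta(hours=h),
                "event_kind": "caabu",
                "confirmed": 1,
            }
            for h in event_offsets_h
        ],
        columns=["patient_id", "event_time", "event_kind", "confirmed"],
    )
    if events.empty:
        events = events.astype({"confirmed": int})
    return RawEhrExtract(patients, pd.DataFrame(rows), events)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
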