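import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import riskvalid as rv

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return rv.load_cohort_config()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """A modest calibrated synthetic pooled cohort (~6000 subjects)."""
    cohort, model = rv.generate_cohort(default_config, seed=123, n_total=6000)
    return cohort, model


@pytest.fixture(scope="session")
def men_cohort(default_config):
    """Men-only calibrated cohort, n ~ 20000, for metric-level checks."""
    cohort, model = rv.generate_cohort(default_config, seed=77, sex="male",
                                       n_total=20000)
    return cohort, model


@pytest.fixture(scope="session")
def independent_cohort(default_config):
    """Men-only cohort with covariate-independent censoring (single 10-year
    horizon plus uniform dropout), calibrated on the mean true risk — the
    clean setting where pooled KM is consistent for the mean model risk."""
    factors = rv.generate_risk_factors(default_config, seed=31, sex="male",
                                       n_total=20000)
    model = rv.calibrate_to_targets(rv.GloboriskModel(), factors,
                                    default_config.target_10yr_risk)
    cohort = rv.simulate_outcomes(factors, model, seed=32,
                                  dropout_rate=0.2)
    return cohort, model


@pytest.fixture()
def toy_subjects():
    """Six hand-written subjects spanning both sexes."""
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(6)],
        "sex": ["male", "male", "male", "female", "female", "female"],
        "age": [55.0, 62.0, 48.0, 55.0, 70.0, 44.0],
        "sbp": [140.0, 125.0, 118.0, 150.0, 135.0, 110.0],
        "tc": [230.0, 210.0, 195.0, 250.0, 220.0, 180.0],
        "smoking": [1, 0, 1, 0, 0, 1],
        "diabetes": [0, 1, 0, 0, 1, 0],
    })


def brute_force_cindex(times, events, risks):
    """Exhaustive Harrell pair enumeration (oracle for small fixtures)."""
    conc = disc = tied = 0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, ei, ej = times[i], times[j], events[i], events[j]
            if ti == tj:
                if ei == ej:
                    continue  # tied times, same status: not comparable
                ev, other = (i, j) if ei else (j, i)
            else:
                a, b = (i, j) if ti < tj else (j, i)
                if not events[a]:
                    continue  # shorter time censored: unusable
                ev, other = a, b
            if risks[ev] > risks[other]:
                conc += 1
            elif risks[ev] < risks[other]:
                disc += 1
            else:
                tied += 1
    total = conc + disc + tied
    return (conc + 0.5 * tied) / total if total else np.nan
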