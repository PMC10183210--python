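import numpy as np
import pandas as pd
import pytest

import orcaforage as of


@pytest.fixture(scope="session")
def cohort():
    """The packaged 52-deployment summary table."""
    return of.load_deployment_fixture()


@pytest.fixture(scope="session")
def cohort_frame(cohort):
    return of.records_to_frame(cohort)


@pytest.fixture(scope="session")
def adult_female_frame(cohort):
    return of.records_to_frame([r for r in cohort if r.sex == "F" and r.adult])


@pytest.fixture(scope="session")
def sim_deployment():
    """One moderately busy simulated deployment shared across tests."""
    cfg = of.SimulationConfig(
        seed=11, duration_h=1.0, sampling_rate=10.0, dive_rate=15.0, capture_rate=5.0
    )
    return cfg, of.simulate_deployment(cfg)


def flat_series(n=12000, fs=10.0, depth=None):
    """A quiet surface series with optional injected depth profile."""
    rng = np.random.default_rng(0)
    d = np.zeros(n) if depth is None else np.asarray(depth, dtype=float)
    return of.SensorSeries(
        sampling_rate=fs,
        depth=d,
        accel=rng.normal(0, 0.01, (n, 3)),
        pitch=np.zeros(n),
        roll=np.zeros(n),
        heading=np.zeros(n),
    )
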