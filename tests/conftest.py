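import warnings

import numpy as np
import pytest

import driftdive as dd

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_trip():
    """A 12-day labelled trip shared by the read-only tests."""
    cfg = dd.TripConfig(n_days=12, dives_per_day=40, seed=101)
    profiles, labels, truth = dd.simulate_trip(cfg)
    return profiles, labels, truth


@pytest.fixture(scope="session")
def label_map(small_trip):
    _, labels, _ = small_trip
    return {l.dive_id: l for l in labels}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_profile(rng, n=None, dive_id="rand"):
    """A random valid dive profile: surface-bounded positive depths."""
    n = n or int(rng.integers(8, 51))
    times = np.arange(n) * 30.0
    interior = np.abs(np.cumsum(rng.normal(0, 25.0, n - 2))) + rng.uniform(5, 50)
    depths = np.concatenate(([0.0], interior, [0.0]))
    return dd.HighResProfile(dive_id=dive_id, times=times, depths=depths)
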