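import numpy as np
import pandas as pd
import pytest

from cohortsampling import CategoryLevels, desk_scale, simulate_cohort


@pytest.fixture(scope="session")
def levels():
    return CategoryLevels()


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale scenario config (prevalence 0.05, strong confounding)."""
    return desk_scale(n=20_000)


@pytest.fixture(scope="session")
def desk_cohort(desk_config):
    """One 20k-subject confounded cohort shared across tests."""
    return simulate_cohort(desk_config, seed=11)


@pytest.fixture
def toy_cohort(levels):
    """A small hand-assembled cohort: 5 exposed (2 cases), 20 unexposed (4 cases)."""
    rng = np.random.default_rng(42)
    n = 25
    exposure = np.r_[np.ones(5, dtype=int), np.zeros(20, dtype=int)]
    event = np.zeros(n, dtype=int)
    event[[0, 3]] = 1            # exposed cases
    event[[6, 10, 15, 22]] = 1   # unexposed cases
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "exposure": exposure,
        "sex": rng.choice(levels.sex, n),
        "age": rng.uniform(20, 60, n),
        "race": rng.choice(levels.race, n),
        "state": rng.choice(levels.state, n),
        "period": rng.choice(levels.period, n),
        "time": np.where(event == 1, rng.uniform(0.5, 4.5, n), 5.0),
        "event": event,
    })


def make_rows(start, stop, event, group, weight, ids=None):
    n = len(stop)
    return pd.DataFrame({
        "id": ids if ids is not None else [str(i) for i in range(n)],
        "start": np.asarray(start, dtype=float),
        "stop": np.asarray(stop, dtype=float),
        "event": np.asarray(event, dtype=int),
        "group": np.asarray(group, dtype=int),
        "weight": np.asarray(weight, dtype=float),
    })
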