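"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """A generic mixed-type table used by design/encoding tests."""
    n = 400
    return pd.DataFrame(
        {
            "age": rng.integers(0, 100, n).astype(float),
            "gender": rng.choice(["M", "F"], n),
            "region": rng.choice(["north", "east", "west", "south"], n),
            "x": rng.normal(0.0, 1.0, n),
            "y": rng.normal(2.0, 1.5, n),
        }
    )


@pytest.fixture(scope="session")
def recovery_fit():
    """One fitted recovery-scenario bundle shared across tests."""
    from popsynth.model import SequentialSynthesizer
    from popsynth.scenarios import recovery_plan, recovery_truth_config
    from popsynth.truth import simulate_truth

    truth = simulate_truth(recovery_truth_config(n_population=20_000, rng_seed=7))
    res = SequentialSynthesizer(truth.data, recovery_plan()).fit()
    return truth, res
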