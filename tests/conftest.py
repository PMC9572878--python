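import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acwr_bayes.robust_compare import MCMCSettings
from acwr_bayes.synthdata import SyntheticConfig, generate_team_season

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def season():
    """One synthetic team season (sessions, injuries, observations), fixed seed."""
    return generate_team_season(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def observations(season):
    return season[2]


@pytest.fixture
def fast_mcmc():
    """Short chains for structural tests; convergence checking off."""
    return MCMCSettings(n_chains=4, n_iterations=2500, warmup=1000, seed=123, check=False)


@pytest.fixture
def toy_sessions():
    """5 weeks of one-session weeks (60 min at RPE 5 = 300 AU) for player A."""
    return pd.DataFrame(
        {
            "player_id": ["A"] * 5,
            "week": [1, 2, 3, 4, 5],
            "day": [2] * 5,
            "duration_min": [60.0] * 5,
            "rpe": [5.0] * 5,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
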