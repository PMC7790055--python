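import numpy as np
import pytest

from hbewa import (
    PATENT_RACE,
    EWAParams,
    SessionData,
    SimScenario,
    from_frame,
    simulate_dataset,
)
from hbewa.initial import estimate_initial_attractions


@pytest.fixture
def game():
    return PATENT_RACE


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_session(rng, game, role=0, g=20, start=6, participant="P001", session=1):
    return SessionData(
        participant=participant,
        session=session,
        role=role,
        choices=rng.integers(0, game.n_actions(role), g),
        opponent_choices=rng.integers(0, game.n_actions(1 - role), g),
        start=start,
    )


def random_params(rng, lam_scale=2.0):
    return EWAParams(
        delta=rng.uniform(0.05, 0.95),
        lam=rng.gamma(2.0, lam_scale / 2.0),
        phi=rng.uniform(0.05, 0.95),
        rho=rng.uniform(0.05, 0.95),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study reused by io/inference tests."""
    sc = SimScenario(n_participants=4, n_sessions=2, n_rounds=30, seed=5)
    data, truth, init = simulate_dataset(sc)
    return data, truth, init


@pytest.fixture(scope="session")
def small_gamedata(small_dataset):
    data, _, _ = small_dataset
    gd = from_frame(data)
    init = estimate_initial_attractions(gd.sessions, gd.game)
    return gd, init
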