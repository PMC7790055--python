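import numpy as np
import pytest

from hbewa import (
    DEFAULT_OPPONENT_POOL,
    DEFAULT_SHARED_TRUTH,
    FAMILIES,
    SimScenario,
    choice_probabilities,
    simulate_dataset,
    simulate_opponents,
)
from hbewa.simulate import DEFAULT_CORRELATION


class TestSimulateOpponents:
    def test_degenerate_pool_is_constant(self, rng):
        pool = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
        seq = simulate_opponents("pool", 50, rng, pool)
        assert (seq == 3).all()

    def test_uniform_pool_frequencies(self):
        rng = np.random.default_rng(8)
        pool = np.full(6, 1 / 6)
        seq = simulate_opponents("pool", 10_000, rng, pool)
        freqs = np.bincount(seq, minlength=6) / 10_000
        np.testing.assert_allclose(freqs, 1 / 6, atol=0.02)

    def test_invalid_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="probability"):
            simulate_opponents("pool", 10, rng, np.array([0.5, 0.6]))


class TestSimulateDataset:
    def test_shared_scenario_has_four_distinct_truths(self):
        sc = SimScenario(n_participants=5, n_sessions=2, n_rounds=10, seed=1)
        _, truth, _ = simulate_dataset(sc)
        assert truth.groupby("family")["value"].nunique().eq(1).all()
        assert len(truth["value"].unique()) == 4

    def test_variability_scenario_varies_by_session(self):
        sc = SimScenario(n_participants=5, n_sessions=2, n_rounds=10,
                         variability=True, seed=1)
        _, truth, _ = simulate_dataset(sc)
        assert truth.groupby("family")["value"].nunique().gt(1).all()

    def test_same_seed_reproduces_exactly(self):
        sc = SimScenario(n_participants=3, n_sessions=2, n_rounds=15,
                         variability=True, seed=123)
        a_data, a_truth, _ = simulate_dataset(sc)
        b_data, b_truth, _ = simulate_dataset(sc)
        assert a_data.equals(b_data)
        assert a_truth.equals(b_truth)

    def test_choices_respect_role_action_spaces(self, game):
        sc = SimScenario(n_participants=4, n_sessions=2, n_rounds=25, seed=2)
        data, _, _ = simulate_dataset(sc)
        for role, grp in data.groupby("role"):
            assert grp["choice"].between(0, game.endowment(int(role))).all()
            opp_max = game.endowment(game.opposing(int(role)))
            assert grp["opponent_choice"].between(0, opp_max).all()

    def test_roles_swap_between_sessions(self):
        sc = SimScenario(n_participants=4, n_sessions=2, n_rounds=5, seed=3)
        data, _, _ = simulate_dataset(sc)
        roles = data.groupby(["participant", "session"])["role"].first().unstack()
        assert (roles[1] != roles[2]).all()

    def test_degenerate_softmax_plays_argmax(self, game):
        """A near-infinite sensitivity with spread initial attractions makes
        every round-1 choice the argmax strategy."""
        from hbewa import EWAParams
        from hbewa.initial import InitialConditions

        truth = EWAParams(delta=0.5, lam=1e6, phi=1.0, rho=1.0)
        init = InitialConditions(
            v0={
                (1, 0): np.array([0.0, 1.0, 0.2, -0.5, 0.1]),
                (1, 1): np.array([0.3, -1.0, 0.0, 2.0, 0.1, 0.4]),
            }
        )
        sc = SimScenario(n_participants=6, n_sessions=1, n_rounds=1,
                         truth=truth, initial_conditions=init, seed=4)
        data, _, _ = simulate_dataset(sc)
        for _, row in data.iterrows():
            v0 = init.for_session(int(row["session"]), int(row["role"]))
            assert int(row["choice"]) == int(np.argmax(v0))

    def test_selfplay_mode_produces_valid_sequences(self, game):
        sc = SimScenario(n_participants=3, n_sessions=2, n_rounds=20,
                         opponent_mode="selfplay", seed=5)
        data, _, _ = simulate_dataset(sc)
        for role, grp in data.groupby("role"):
            opp_max = game.endowment(game.opposing(int(role)))
            assert grp["opponent_choice"].between(0, opp_max).all()

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            SimScenario(n_participants=0)
        with pytest.raises(ValueError):
            SimScenario(opponent_mode="telepathy")
        with pytest.raises(ValueError, match="not a distribution"):
            SimScenario(opponent_pool={0: np.array([0.5, 0.6])})


class TestGenerativeConsistency:
    def test_constant_attraction_agent_matches_softmax_frequencies(self, game):
        """Simulated choice frequencies of an agent with frozen attractions
        converge to the softmax probabilities."""
        rng = np.random.default_rng(11)
        v = np.array([0.0, 0.5, 1.0, 0.2, -0.3])
        lam = 1.3
        p = choice_probabilities(v, lam, game, 0)
        g = 20_000
        z = lam * v
        probs = np.exp(z - z.max())
        probs /= probs.sum()
        draws = rng.choice(5, size=g, p=probs)
        freqs = np.bincount(draws, minlength=5) / g
        np.testing.assert_allclose(freqs, p, atol=0.02)

    def test_hier_truth_correlation_matrix_is_positive_definite(self):
        assert np.linalg.eigvalsh(DEFAULT_CORRELATION).min() > 0

    def test_default_pools_are_distributions(self):
        for role, p in DEFAULT_OPPONENT_POOL.items():
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_truth_table_covers_every_session_and_family(self):
        sc = SimScenario(n_participants=3, n_sessions=2, n_rounds=5, seed=6)
        data, truth, _ = simulate_dataset(sc)
        assert set(truth["family"]) == set(FAMILIES)
        assert len(truth) == 3 * 2 * 4
        shared = truth[truth["family"] == "delta"]["value"].iloc[0]
        assert shared == pytest.approx(DEFAULT_SHARED_TRUTH.delta)
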