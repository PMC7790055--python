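import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hbewa import (
    AttractionState,
    EWAParams,
    GameSpec,
    SessionData,
    attractions_closed,
    choice_probabilities,
    experience_weight_closed,
    session_log_likelihood,
    update_state,
)
from conftest import random_params, random_session


class TestUpdateState:
    def test_belief_learning_first_round_equals_payoffs(self, game):
        """With delta=1, phi=1, rho=0 and zero priors, round-1 attractions
        are exactly the payoff column against the observed opponent play."""
        params = EWAParams(delta=1.0, lam=1.0, phi=1.0, rho=0.0)
        state = AttractionState(V=np.zeros(5), N=1.0)
        new = update_state(state, params, own_choice=1, opponent_choice=2, game=game, role=0)
        expected = [game.payoff(0, k, 2) for k in range(5)]
        assert new.N == 1.0
        np.testing.assert_allclose(new.V, expected)

    def test_reinforcement_only_ignores_unchosen(self, game, rng):
        """delta=0: unchosen strategies receive zero reinforcement, so their
        attractions change only through the phi/N decay."""
        params = EWAParams(delta=0.0, lam=1.0, phi=0.7, rho=0.4)
        state = AttractionState(V=rng.normal(size=5), N=1.3)
        new = update_state(state, params, 2, 3, game, 0)
        n_new = 0.4 * 1.3 + 1.0
        decayed = 0.7 * 1.3 * state.V / n_new
        unchosen = [k for k in range(5) if k != 2]
        np.testing.assert_allclose(new.V[unchosen], decayed[unchosen])
        assert new.V[2] != pytest.approx(decayed[2])

    def test_rho_zero_pins_experience_weight(self, game, rng):
        params = EWAParams(delta=0.5, lam=1.0, phi=0.5, rho=0.0)
        state = AttractionState(V=np.zeros(5), N=7.0)
        for t in range(4):
            state = update_state(state, params, 1, 1, game, 0)
            assert state.N == 1.0

    def test_invalid_choice_reports_round(self, game):
        params = EWAParams(0.5, 1.0, 0.5, 0.5)
        state = AttractionState(V=np.zeros(5), N=1.0, t=3)
        with pytest.raises(ValueError, match="round 4"):
            update_state(state, params, 9, 0, game, 0)


class TestExperienceWeightClosed:
    @pytest.mark.parametrize(
        "rho,n0,t,expected",
        [(0.5, 1.0, 2, 1.75), (0.0, 1.0, 3, 1.0), (1.0, 1.0, 4, 5.0)],
    )
    def test_hand_values(self, rho, n0, t, expected):
        assert experience_weight_closed(rho, n0, t) == pytest.approx(expected)

    def test_matches_recursion(self, rng):
        for _ in range(50):
            rho, n0 = rng.random(), rng.gamma(2.0)
            n = n0
            for t in range(1, 15):
                n = rho * n + 1.0
                assert experience_weight_closed(rho, n0, t) == pytest.approx(n, rel=1e-12)

    def test_negative_round_rejected(self):
        with pytest.raises(ValueError):
            experience_weight_closed(0.5, 1.0, -1)


class TestAttractionsClosed:
    def test_round_zero_returns_priors(self, game, rng):
        sd = random_session(rng, game)
        v0 = rng.normal(size=5)
        out = attractions_closed(
            random_params(rng), v0, 1.0, sd.choices, sd.opponent_choices, 0, game, 0
        )
        np.testing.assert_array_equal(out, v0)

    def test_phi_zero_erases_history(self, game, rng):
        """phi=0: only the current round's reinforcement survives."""
        sd = random_session(rng, game, g=10)
        params = EWAParams(delta=0.3, lam=1.0, phi=0.0, rho=0.6)
        t = 7
        v0 = rng.normal(size=5)
        out = attractions_closed(params, v0, 1.0, sd.choices, sd.opponent_choices, t, game, 0)
        pi = game.payoff_matrix(0)[:, sd.opponent_choices[t - 1]]
        onehot = np.eye(5)[sd.choices[t - 1]]
        f_t = (0.3 + 0.7 * onehot) * pi
        np.testing.assert_allclose(out, f_t / experience_weight_closed(0.6, 1.0, t))

    def test_matches_recursion_oracle(self, game, rng):
        for role in (0, 1):
            for _ in range(20):
                g = 20
                sd = random_session(rng, game, role=role, g=g)
                params = random_params(rng)
                v0 = rng.normal(size=game.n_actions(role))
                state = AttractionState(V=v0, N=1.0)
                for t in range(g):
                    state = update_state(
                        state, params, sd.choices[t], sd.opponent_choices[t], game, role
                    )
                closed = attractions_closed(
                    params, v0, 1.0, sd.choices, sd.opponent_choices, g, game, role
                )
                np.testing.assert_allclose(closed, state.V, rtol=1e-10, atol=1e-10)

    def test_mismatched_sequences_rejected(self, game, rng):
        with pytest.raises(ValueError, match="mismatch"):
            attractions_closed(
                random_params(rng), np.zeros(5), 1.0,
                np.zeros(4, dtype=int), np.zeros(5, dtype=int), 3, game, 0,
            )


class TestChoiceProbabilities:
    def test_lambda_zero_is_uniform(self, game, rng):
        p = choice_probabilities(rng.normal(size=5), 0.0, game, 0)
        np.testing.assert_allclose(p, np.full(5, 0.2))

    def test_two_strategy_log2_example(self):
        toy = GameSpec(prize=2, endowments=(1, 1))
        p = choice_probabilities(np.array([0.0, 1.0]), np.log(2.0), toy, 0)
        np.testing.assert_allclose(p, [1 / 3, 2 / 3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        game = GameSpec()
        role = int(rng.integers(2))
        V = rng.normal(0, 5, game.n_actions(role))
        p = choice_probabilities(V, float(rng.gamma(2.0)), game, role)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0)

    def test_sharper_lambda_favours_argmax(self, game, rng):
        V = rng.normal(size=6)
        best = V.argmax()
        probs = [
            choice_probabilities(V, lam, game, 1)[best] for lam in (0.0, 0.5, 1.0, 3.0, 10.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_overflow_safe_at_large_lambda(self, game):
        p = choice_probabilities(np.array([0.0, 500.0, 0.0, 0.0, 0.0]), 10.0, game, 0)
        assert np.isfinite(p).all()
        assert p[1] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self, game):
        with pytest.raises(ValueError, match="does not match"):
            choice_probabilities(np.zeros(5), 1.0, game, 1)


class TestSessionLogLikelihood:
    def test_uniform_choice_probability_case(self, game, rng):
        """lam=0 makes every weak-role choice probability 1/5; with 20
        rounds and the likelihood starting at round 6, 15 rounds count."""
        sd = random_session(rng, game, role=0, g=20, start=6)
        params = EWAParams(delta=0.5, lam=0.0, phi=0.5, rho=0.5)
        total, per_round = session_log_likelihood(sd, params, np.zeros(5), 1.0, game)
        assert len(per_round) == 15
        assert total == pytest.approx(15 * np.log(1 / 5))

    def test_confident_correct_choice_has_near_zero_loss(self, game):
        v0 = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
        sd = SessionData("p", 1, 0, [1], [0], start=1)
        params = EWAParams(delta=0.5, lam=50.0, phi=0.5, rho=0.5)
        total, _ = session_log_likelihood(sd, params, v0, 1.0, game)
        assert total == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_closed_form_equals_recursion(self, seed):
        rng = np.random.default_rng(seed)
        game = GameSpec()
        role = int(rng.integers(2))
        sd = random_session(rng, game, role=role, g=int(rng.integers(8, 40)))
        params = random_params(rng)
        v0 = rng.normal(size=game.n_actions(role))
        a, pa = session_log_likelihood(sd, params, v0, 1.0, game, method="closed")
        b, pb = session_log_likelihood(sd, params, v0, 1.0, game, method="recursive")
        assert a == pytest.approx(b, rel=1e-10, abs=1e-10)
        np.testing.assert_allclose(pa, pb, rtol=1e-10, atol=1e-10)

    def test_accelerated_path_matches_vectorised_closed_form(self, game, rng):
        """The compiled per-round kernel and the vectorised closed form are
        the same algebra; results agree to machine precision."""
        from hbewa.ewa import SessionDesign

        sd = random_session(rng, game, role=1, g=40)
        des = SessionDesign(sd, game, rng.normal(size=6), 1.3)
        for _ in range(50):
            p = (rng.random(), float(rng.gamma(2.0)), rng.random(), rng.random())
            a = des.per_round_logp(*p)
            b = des._per_round_logp_numpy(*p)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_state_evolves_through_pre_likelihood_rounds(self, game, rng):
        """Changing a round-2 observation changes round-6 probabilities even
        though round 2 itself does not enter the likelihood sum."""
        sd = random_session(rng, game, g=10, start=6)
        params = random_params(rng)
        a, _ = session_log_likelihood(sd, params, np.zeros(5), 1.0, game)
        altered = SessionData(
            sd.participant, sd.session, sd.role,
            sd.choices, np.where(np.arange(10) == 1,
                                 (sd.opponent_choices + 3) % 6, sd.opponent_choices),
            start=6,
        )
        b, _ = session_log_likelihood(altered, params, np.zeros(5), 1.0, game)
        assert a != pytest.approx(b)

    def test_degenerate_probability_warns_not_raises(self, game, rng):
        sd = random_session(rng, game, g=8, start=1)
        params = EWAParams(delta=0.5, lam=np.inf, phi=0.5, rho=0.5)
        with pytest.warns(RuntimeWarning, match="-inf"):
            total, _ = session_log_likelihood(sd, params, np.zeros(5), 1.0, game)
        assert total == -np.inf

    def test_attractions_bounded_by_payoffs_when_phi_equals_rho(self, game, rng):
        """With phi = rho, attractions settle inside the payoff range."""
        lo, hi = game.payoff_matrix(0).min(), game.payoff_matrix(0).max()
        for _ in range(10):
            c = rng.uniform(0.1, 0.95)
            params = EWAParams(delta=rng.random(), lam=1.0, phi=c, rho=c)
            sd = random_session(rng, game, g=60)
            v = attractions_closed(
                params, rng.normal(0, 20, 5), 1.0,
                sd.choices, sd.opponent_choices, 60, game, 0,
            )
            assert v.min() >= lo - 1e-9
            assert v.max() <= hi + 1e-9
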