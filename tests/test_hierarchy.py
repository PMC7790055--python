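import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbewa import (
    FAMILIES,
    HierParams,
    build_design,
    inverse_link,
    link,
    log_prior,
    parameter_from_linear_predictor,
    sample_random_effects,
)


class TestLinks:
    def test_logit_centre(self):
        assert link(0.5, "delta") == pytest.approx(0.0)
        assert link(0.5, "phi") == pytest.approx(0.0)
        assert link(0.5, "rho") == pytest.approx(0.0)

    def test_log_link_for_sensitivity(self):
        assert inverse_link(0.0, "lam") == pytest.approx(1.0)
        assert link(np.e, "lam") == pytest.approx(1.0)

    def test_bijection(self, rng):
        for family in FAMILIES:
            vals = rng.gamma(2.0, 1.0, 1000) if family == "lam" else rng.random(1000)
            vals = np.clip(vals, 1e-9, None if family == "lam" else 1 - 1e-9)
            for v in vals[:: 50]:
                assert inverse_link(link(v, family), family) == pytest.approx(v, rel=1e-12)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            link(1.5, "delta")
        with pytest.raises(ValueError):
            link(-0.1, "lam")
        with pytest.raises(ValueError, match="unknown parameter family"):
            link(0.5, "kappa")


class TestLinearPredictor:
    def test_zero_predictor_hits_link_centre(self):
        x, z = np.array([1.0, 0.0]), np.array([0.0])
        beta, gamma = np.zeros(2), np.zeros(1)
        assert parameter_from_linear_predictor(x, z, beta, gamma, 0, 0, "delta") == 0.5
        assert parameter_from_linear_predictor(x, z, beta, gamma, 0, 0, "lam") == 1.0

    def test_intercept_recovers_target_value(self):
        x, z = np.array([1.0]), np.array([0.0])
        beta = np.array([link(0.8, "rho")])
        out = parameter_from_linear_predictor(x, z, beta, np.zeros(1), 0, 0, "rho")
        assert out == pytest.approx(0.8)

    def test_always_in_support(self, rng):
        for family in FAMILIES:
            for _ in range(100):
                x = rng.normal(0, 50, 3)
                out = parameter_from_linear_predictor(
                    x, rng.normal(0, 50, 2), rng.normal(0, 5, 3), rng.normal(0, 5, 2),
                    rng.normal(0, 50), rng.normal(0, 50), family,
                )
                if family == "lam":
                    assert out >= 0
                else:
                    assert 0.0 <= out <= 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            parameter_from_linear_predictor(
                np.ones(3), np.ones(2), np.ones(2), np.ones(2), 0, 0, "delta"
            )

    def test_session_difference_only_through_z_and_residual(self, rng):
        """Two sessions of one participant share x, beta and theta, so their
        link-scale gap is exactly the z-contrast plus residual difference."""
        x = rng.normal(size=3)
        beta, gamma = rng.normal(size=3), rng.normal(size=2)
        theta = rng.normal()
        z1, z2 = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        e1, e2 = rng.normal(size=2)
        g1 = link(parameter_from_linear_predictor(x, z1, beta, gamma, theta, e1, "phi"), "phi")
        g2 = link(parameter_from_linear_predictor(x, z2, beta, gamma, theta, e2, "phi"), "phi")
        assert g1 - g2 == pytest.approx((z1 - z2) @ gamma + (e1 - e2), rel=1e-9)


class TestRandomEffects:
    def test_zero_variance_limit(self, rng):
        theta = sample_random_effects(np.eye(4) * 1e-20, 50, rng)
        np.testing.assert_allclose(theta, 0.0, atol=1e-8)

    def test_identity_covariance_recovered(self):
        rng = np.random.default_rng(99)
        theta = sample_random_effects(np.eye(4), 10_000, rng)
        np.testing.assert_allclose(theta.mean(axis=0), 0.0, atol=0.05)
        np.testing.assert_allclose(np.cov(theta.T), np.eye(4), atol=0.1)

    def test_seeded_determinism(self):
        a = sample_random_effects(np.eye(4), 5, np.random.default_rng(7))
        b = sample_random_effects(np.eye(4), 5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_non_positive_definite_rejected(self, rng):
        bad = np.ones((4, 4))  # rank 1
        bad[0, 1] = 2.0
        bad[1, 0] = 2.0
        with pytest.raises(ValueError, match="positive definite"):
            sample_random_effects(bad, 3, rng)


def _hier_params(sigma_eps=(1.0, 1.0, 1.0, 1.0), Sigma=None):
    return HierParams(
        beta=np.zeros((4, 3)),
        gamma=np.zeros((4, 2)),
        sigma_eps=np.array(sigma_eps),
        Sigma=np.eye(4) if Sigma is None else Sigma,
        theta=np.zeros((2, 4)),
    )


class TestLogPrior:
    def test_residual_scale_outside_uniform_support(self):
        assert log_prior(_hier_params(sigma_eps=(1500.0, 1, 1, 1))) == -np.inf

    def test_coefficient_mode_contribution(self):
        """Moving one beta off 0 lowers the prior by the N(0,100^2) log ratio."""
        base = _hier_params()
        moved = _hier_params()
        moved.beta[0, 0] = 200.0
        diff = log_prior(base) - log_prior(moved)
        expected = stats.norm.logpdf(0, scale=100) - stats.norm.logpdf(200, scale=100)
        assert diff == pytest.approx(expected)

    def test_wishart_prior_correlations_marginally_uniform(self):
        """Sigma^-1 ~ Wishart(I_4, 5) implies marginally uniform prior
        correlations on (-1, 1) at df = dim + 1."""
        rng = np.random.default_rng(42)
        draws = stats.wishart.rvs(df=5, scale=np.eye(4), size=4000, random_state=rng)
        sigmas = np.linalg.inv(draws)
        corr = sigmas[:, 0, 1] / np.sqrt(sigmas[:, 0, 0] * sigmas[:, 1, 1])
        stat = stats.kstest(corr, stats.uniform(loc=-1, scale=2).cdf)
        assert stat.pvalue > 0.01


class TestDesign:
    def _records(self):
        return pd.DataFrame(
            {
                "participant": ["A", "A", "B", "B"],
                "session": [1, 2, 1, 2],
                "role": [0, 1, 1, 0],
                "age": [20, 20, 30, 30],
                "sex": [0, 0, 1, 1],
            }
        )

    def test_age_is_centred_and_intercept_present(self):
        d = build_design(self._records())
        assert d.x.shape == (2, 3)
        np.testing.assert_allclose(d.x[:, 0], 1.0)
        assert d.x[:, 1].mean() == pytest.approx(0.0)

    def test_session_and_role_coding(self):
        d = build_design(self._records())
        np.testing.assert_array_equal(d.z[:, 0], [0, 1, 1, 0])   # strong role
        np.testing.assert_array_equal(d.z[:, 1], [1, 0, 1, 0])   # session 1
        np.testing.assert_array_equal(d.participant_index, [0, 0, 1, 1])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="age"):
            build_design(self._records().drop(columns=["age"]))

    def test_shared_reduction_gives_identical_parameters(self, rng):
        """With zero covariate effects, zero residuals and zero random
        effects, every participant-session gets the intercept-implied value."""
        d = build_design(self._records())
        beta = np.array([link(0.35, "delta"), 0.0, 0.0])
        vals = [
            parameter_from_linear_predictor(
                d.x[d.participant_index[s]], d.z[s] * 0.0, beta, np.zeros(2), 0.0, 0.0, "delta"
            )
            for s in range(4)
        ]
        assert len({round(v, 12) for v in vals}) == 1
        assert vals[0] == pytest.approx(0.35)
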