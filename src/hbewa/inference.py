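"""Posterior sampling for the three estimation regimes.

* :func:`fit_shared` — one parameter quadruple for every
  participant-session (the representative-agent model), with
  Uniform(0, 1) priors on delta, phi, rho and Gamma(0.01, 0.01) on lam.
* :func:`fit_unique` — an independent quadruple per participant-session
  under the same weak priors, with no pooling and no covariates.
* :func:`fit_full` — the hierarchical regression model: link-scale
  session parameters tied together by covariate effects, correlated
  participant random effects (MVN with inverse-Wishart-conjugate
  covariance) and session residuals.

The sampling scheme is Metropolis-within-Gibbs: adaptive random-walk
Metropolis on link-transformed session parameters (and on log sigma_eps),
exact conjugate Gibbs draws for the Gaussian regression layer (beta,
gamma, theta) and for Sigma given theta, plus an occasional joint
(sigma_eps, residual) rescaling move that lets the residual-scale
hierarchy mix across orders of magnitude.  Proposal scales adapt toward
~0.3 acceptance during burn-in only and are frozen afterwards, so the
post-burn-in kernel leaves the posterior invariant.

Every fit spot-checks the closed-form likelihood against the round-by-
round recursion on one draw before sampling starts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ewa import FAMILIES, EWAParams, SessionDesign, StackedSessions, session_log_likelihood
from .initial import InitialConditions
from .io import GameData

_ADAPT_WINDOW = 50
_ADAPT_TARGET = 0.3
_HOP_SCALE = 2.0


def _cauchy_logpdf(x: float, loc: float, scale: float) -> float:
    z = (x - loc) / scale
    return -np.log(np.pi * scale * (1.0 + z * z))
_INIT_RETRIES = 10
_RESCALE_EVERY = 10
_SIGMA_UPPER = 1000.0
_COEF_SD = 100.0
_WISHART_DF = 5


# ---------------------------------------------------------------------------
# schedule and results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerSchedule:
    """Chain layout: post-burn-in iterations per chain, burn-in, thinning."""

    chains: int = 2
    iterations: int = 500_000
    burnin: int = 100_000
    thin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chains, self.iterations, self.burnin, self.thin) < 1:
            raise ValueError("chains, iterations, burnin and thin must all be positive")
        if self.iterations % self.thin != 0:
            raise ValueError(
                f"thinning interval {self.thin} must divide the "
                f"{self.iterations} post-burn-in iterations evenly"
            )

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin

    @property
    def retained_total(self) -> int:
        return self.chains * self.retained_per_chain


#: desk-scale schedule used for simulation studies and examples
REDUCED_SCHEDULE = SamplerSchedule(chains=2, iterations=20_000, burnin=4_000, thin=10)


class PosteriorSamples:
    """Thinned multi-chain draws plus pointwise log-likelihoods.

    ``params`` maps scalar parameter names to (chains, retained) arrays;
    ``session_params`` maps each family to a (chains, retained, sessions)
    array of natural-scale participant-session parameters.
    """

    def __init__(
        self,
        model: str,
        schedule: SamplerSchedule,
        params: dict[str, np.ndarray],
        session_params: dict[str, np.ndarray],
        session_keys: list[tuple[str, int]],
        pointwise: np.ndarray | None,
        point_index: pd.DataFrame | None,
    ):
        self.model = model
        self.schedule = schedule
        self.params = params
        self.session_params = session_params
        self.session_keys = session_keys
        self.pointwise = pointwise
        self.point_index = point_index

    # -- access ------------------------------------------------------------

    @property
    def n_retained(self) -> int:
        return self.schedule.retained_total

    def names(self) -> list[str]:
        return list(self.params)

    def draws(self, name: str) -> np.ndarray:
        return self.params[name]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def session_draws(self, family: str) -> np.ndarray:
        """Natural-scale draws, shape (total draws, sessions)."""
        a = self.session_params[family]
        return a.reshape(-1, a.shape[-1])

    def session_posterior_mean(self, family: str) -> dict[tuple[str, int], float]:
        m = self.session_draws(family).mean(axis=0)
        return dict(zip(self.session_keys, m.tolist()))

    def session_intervals(
        self, family: str, level: float = 0.95
    ) -> dict[tuple[str, int], tuple[float, float]]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.session_draws(family), [a, 1.0 - a], axis=0)
        return {k: (float(l), float(h)) for k, l, h in zip(self.session_keys, lo, hi)}

    def pointwise_matrix(self) -> np.ndarray:
        """(total draws, points) log-likelihood matrix for WAIC."""
        if self.pointwise is None:
            raise ValueError("no pointwise log-likelihoods (prior-only run?)")
        return self.pointwise.reshape(-1, self.pointwise.shape[-1])

    # -- diagnostics ---------------------------------------------------------

    def _iter_series(self):
        for name, a in self.params.items():
            for c in range(a.shape[0]):
                yield name, c, a[c]
        for fam, a in self.session_params.items():
            for s, key in enumerate(self.session_keys):
                for c in range(a.shape[0]):
                    yield f"{fam}[{key[0]},{key[1]}]", c, a[c, :, s]

    def diagnostics(self) -> pd.DataFrame:
        """Geweke z and effective sample size per parameter per chain."""
        rows = []
        for name, c, x in self._iter_series():
            z = geweke_z(x) if len(x) >= 100 else np.nan
            ess = effective_sample_size(x)
            rows.append(
                {
                    "parameter": name,
                    "chain": c,
                    "geweke_z": z,
                    "ess": ess,
                    "degenerate": bool(np.isnan(ess)),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, a in self.params.items():
            x = a.reshape(-1)
            q = np.quantile(x, [0.025, 0.5, 0.975])
            rows.append(
                {
                    "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
                    "q2.5": q[0], "median": q[1], "q97.5": q[2],
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) table of all draws."""
        frames = []
        for name, c, x in self._iter_series():
            frames.append(
                pd.DataFrame(
                    {"chain": c, "draw": np.arange(len(x)), "parameter": name, "value": x}
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1].real / n
    return acov


def _spectral_density_zero(x: np.ndarray) -> float:
    """Long-run variance via a Bartlett-windowed autocovariance sum."""
    n = len(x)
    lag = max(1, int(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    lag = min(lag, n - 1)
    acov = _autocovariances(x, lag)
    w = 1.0 - np.arange(1, lag + 1) / (lag + 1.0)
    return float(acov[0] + 2.0 * np.sum(w * acov[1:]))


def geweke_z(x, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: early-vs-late segment means scaled by their
    spectral-density-at-zero variance estimates.  Returns NaN for a
    degenerate (zero-variance) chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError(f"chain too short for the Geweke diagnostic ({n} < 100)")
    a = x[: int(first * n)]
    b = x[-int(last * n):]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    var = _spectral_density_zero(a) / len(a) + _spectral_density_zero(b) / len(b)
    if var <= 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(var))


def effective_sample_size(x) -> float:
    """ESS = N / (1 + 2 * sum of autocorrelations), with the sum truncated
    at the first negative consecutive pair (initial positive sequence).
    Returns NaN for a degenerate chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"chain too short for an ESS estimate ({n} < 10)")
    acov = _autocovariances(x, n - 1)
    if acov[0] == 0:
        return np.nan
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
        k += 2
    return float(n / (1.0 + 2.0 * s))


# ---------------------------------------------------------------------------
# link-scale transforms and weak session-level priors
# ---------------------------------------------------------------------------

def _sigmoid(u):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-u))


def _natural_quadruple(u: np.ndarray) -> tuple[float, float, float, float]:
    """(delta, lam, phi, rho) from link-scale values (logit, log, logit, logit)."""
    with np.errstate(over="ignore"):
        return (
            float(_sigmoid(u[0])),
            float(np.exp(u[1])),
            float(_sigmoid(u[2])),
            float(_sigmoid(u[3])),
        )


def _log_prior_link(u: float, family: str) -> float:
    """Weak-prior log density on the link scale (Jacobian included).

    Uniform(0,1) on a logit scale is the standard logistic density;
    Gamma(0.01, 0.01) on a log scale is 0.01*u - 0.01*exp(u) (+ const).
    """
    if family == "lam":
        return 0.01 * u - 0.01 * np.exp(min(u, 700.0))
    return -np.logaddexp(0.0, u) - np.logaddexp(0.0, -u)


def _session_seed(base: int, chain: int, participant: str, session: int) -> np.random.Generator:
    key = zlib.crc32(f"{participant}:{session}".encode())
    return np.random.default_rng(np.random.SeedSequence([base, chain, key]))


class _AdaptiveSteps:
    """Per-parameter RW proposal scales tuned toward ~0.3 acceptance
    during burn-in, frozen afterwards."""

    def __init__(self, shape, init=0.3, max_step=2.0):
        self.step = np.full(shape, float(init))
        self.max_step = float(max_step)
        self.acc = np.zeros(shape)
        self.tries = np.zeros(shape)

    def record(self, idx, accepted: bool) -> None:
        self.tries[idx] += 1
        if accepted:
            self.acc[idx] += 1

    def adapt(self) -> None:
        with np.errstate(invalid="ignore"):
            rate = np.where(self.tries > 0, self.acc / np.maximum(self.tries, 1), _ADAPT_TARGET)
        self.step *= np.exp(rate - _ADAPT_TARGET)
        # The cap matters in the hierarchical sampler: in likelihood-flat
        # (saturated-link) regions acceptance stays high regardless of
        # step, and an unbounded step lets chains leap deep into the
        # plateau.  The weak-prior samplers need a generous cap instead —
        # the Gamma(0.01, 0.01) sensitivity prior spans hundreds of
        # log-units.
        np.clip(self.step, 1e-4, self.max_step, out=self.step)
        self.acc[...] = 0
        self.tries[...] = 0


def _safe_loglik(design: SessionDesign, natural) -> tuple[float, np.ndarray]:
    total, logp = design.log_likelihood(*natural)
    if not np.isfinite(total):
        return -np.inf, logp
    return total, logp


def _check_closed_vs_recursive(data: GameData, init: InitialConditions, natural) -> None:
    sd = data.sessions[0]
    v0 = init.for_session(sd.session, sd.role)
    design = SessionDesign(sd, data.game, v0, init.n0)
    total, _ = design.log_likelihood(*natural)
    ref, _ = session_log_likelihood(
        sd, EWAParams(*natural), v0, init.n0, data.game, method="recursive"
    )
    if np.isfinite(total) and abs(total - ref) > 1e-8 * max(1.0, abs(ref)):
        raise RuntimeError(
            f"closed-form likelihood disagrees with the recursion: {total} vs {ref}"
        )


_DEFAULT_LINK_INIT = np.array([0.0, 0.0, 0.4, 0.4])  # delta .5, lam 1, phi/rho ~.6


def _build_designs(data: GameData, init: InitialConditions) -> list[SessionDesign]:
    return [
        SessionDesign(sd, data.game, init.for_session(sd.session, sd.role), init.n0)
        for sd in data.sessions
    ]


def _point_index(data: GameData) -> pd.DataFrame:
    rows = []
    for sd in data.sessions:
        for t in range(sd.start, sd.n_rounds + 1):
            rows.append({"participant": sd.participant, "session": sd.session, "round": t})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared-parameter model
# ---------------------------------------------------------------------------

def fit_shared(
    data: GameData,
    init: InitialConditions,
    schedule: SamplerSchedule,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Posterior sampling under one shared quadruple for all sessions."""
    designs = _build_designs(data, init)
    stacked = StackedSessions(designs)
    n_points = sum(d.n_points for d in designs)
    R = schedule.retained_per_chain

    par = {f: np.empty((schedule.chains, R)) for f in FAMILIES}
    pointwise = None if prior_only else np.empty((schedule.chains, R, n_points))

    for chain in range(schedule.chains):
        rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, chain]))
        for attempt in range(_INIT_RETRIES):
            u = _DEFAULT_LINK_INIT + 0.2 * rng.standard_normal(4)
            if prior_only:
                ll, per = 0.0, None
                break
            ll, per = stacked.log_likelihood(*_natural_quadruple(u))
            if np.isfinite(ll):
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initial state")
        if not prior_only:
            _check_closed_vs_recursive(data, init, _natural_quadruple(u))

        steps = _AdaptiveSteps(4, max_step=300.0)
        r = 0
        for it in range(schedule.burnin + schedule.iterations):
            for fi, fam in enumerate(FAMILIES):
                prop = u.copy()
                prop[fi] += steps.step[fi] * rng.standard_normal()
                if prior_only:
                    ll_new, per_new = 0.0, None
                else:
                    ll_new, per_new = stacked.log_likelihood(*_natural_quadruple(prop))
                    if not np.isfinite(ll_new):
                        ll_new = -np.inf
                logr = (ll_new - ll) + _log_prior_link(prop[fi], fam) - _log_prior_link(u[fi], fam)
                accepted = np.log(rng.random()) < logr
                if accepted:
                    u, ll, per = prop, ll_new, per_new
                steps.record(fi, accepted)
            if it < schedule.burnin:
                if (it + 1) % _ADAPT_WINDOW == 0:
                    steps.adapt()
            elif (it - schedule.burnin + 1) % schedule.thin == 0:
                nat = _natural_quadruple(u)
                for fi, fam in enumerate(FAMILIES):
                    par[fam][chain, r] = nat[fi]
                if not prior_only:
                    pointwise[chain, r] = np.concatenate(per)
                r += 1
        assert r == R

    S = len(designs)
    session_params = {
        fam: np.broadcast_to(par[fam][:, :, None], (schedule.chains, R, S)).copy()
        for fam in FAMILIES
    }
    return PosteriorSamples(
        model="shared",
        schedule=schedule,
        params=dict(par),
        session_params=session_params,
        session_keys=data.session_keys,
        pointwise=pointwise,
        point_index=None if prior_only else _point_index(data),
    )


# ---------------------------------------------------------------------------
# unique-parameter model
# ---------------------------------------------------------------------------

def fit_unique(
    data: GameData,
    init: InitialConditions,
    schedule: SamplerSchedule,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Independent per-session quadruples under the weak priors.

    Each session is updated from its own seeded random stream, so the
    inference for any one session is identical whether it is fitted alone
    or together with others.
    """
    designs = _build_designs(data, init)
    S = len(designs)
    n_points = sum(d.n_points for d in designs)
    offsets = np.concatenate([[0], np.cumsum([d.n_points for d in designs])])
    R = schedule.retained_per_chain

    session_params = {f: np.empty((schedule.chains, R, S)) for f in FAMILIES}
    pointwise = None if prior_only else np.empty((schedule.chains, R, n_points))

    for chain in range(schedule.chains):
        rngs = [
            _session_seed(schedule.seed, chain, d.data.participant, d.data.session)
            for d in designs
        ]
        u = np.empty((S, 4))
        ll = np.empty(S)
        per: list[np.ndarray | None] = [None] * S
        for s, d in enumerate(designs):
            for attempt in range(_INIT_RETRIES):
                u[s] = _DEFAULT_LINK_INIT + 0.2 * rngs[s].standard_normal(4)
                if prior_only:
                    ll[s] = 0.0
                    break
                ll[s], per[s] = _safe_loglik(d, _natural_quadruple(u[s]))
                if np.isfinite(ll[s]):
                    break
            else:
                raise RuntimeError(
                    f"could not initialize session {d.data.participant}/{d.data.session}"
                )
        if not prior_only:
            _check_closed_vs_recursive(data, init, _natural_quadruple(u[0]))

        steps = _AdaptiveSteps((S, 4), max_step=300.0)
        r = 0
        for it in range(schedule.burnin + schedule.iterations):
            for s, d in enumerate(designs):
                rng = rngs[s]
                for fi, fam in enumerate(FAMILIES):
                    prop = u[s].copy()
                    prop[fi] += steps.step[s, fi] * rng.standard_normal()
                    if prior_only:
                        ll_new, per_new = 0.0, None
                    else:
                        ll_new, per_new = _safe_loglik(d, _natural_quadruple(prop))
                    logr = (
                        (ll_new - ll[s])
                        + _log_prior_link(prop[fi], fam)
                        - _log_prior_link(u[s, fi], fam)
                    )
                    accepted = np.log(rng.random()) < logr
                    if accepted:
                        u[s], ll[s], per[s] = prop, ll_new, per_new
                    steps.record((s, fi), accepted)
            if it < schedule.burnin:
                if (it + 1) % _ADAPT_WINDOW == 0:
                    steps.adapt()
            elif (it - schedule.burnin + 1) % schedule.thin == 0:
                for s in range(S):
                    nat = _natural_quadruple(u[s])
                    for fi, fam in enumerate(FAMILIES):
                        session_params[fam][chain, r, s] = nat[fi]
                    if not prior_only:
                        pointwise[chain, r, offsets[s]: offsets[s + 1]] = per[s]
                r += 1
        assert r == R

    return PosteriorSamples(
        model="unique",
        schedule=schedule,
        params={},
        session_params=session_params,
        session_keys=data.session_keys,
        pointwise=pointwise,
        point_index=None if prior_only else _point_index(data),
    )


# ---------------------------------------------------------------------------
# full hierarchical model
# ---------------------------------------------------------------------------

def fit_full(
    data: GameData,
    init: InitialConditions,
    schedule: SamplerSchedule,
    prior_only: bool = False,
) -> PosteriorSamples:
    """The hierarchical regression model with correlated random effects."""
    designs = _build_designs(data, init)
    S = len(designs)
    des = data.design
    n = des.x.shape[0]
    X = des.x[des.participant_index]          # (S, p_x)
    W = np.concatenate([X, des.z], axis=1)    # (S, p)
    p_x, p_z = des.p_x, des.p_z
    p = p_x + p_z
    WtW = W.T @ W
    pidx = des.participant_index
    counts = np.bincount(pidx, minlength=n).astype(float)
    uniform_counts = np.all(counts == counts[0])

    n_points = sum(d.n_points for d in designs)
    offsets = np.concatenate([[0], np.cumsum([d.n_points for d in designs])])
    R = schedule.retained_per_chain

    coef_names = [
        f"beta_{fam}[{nm}]" for fam in FAMILIES for nm in des.x_names
    ] + [f"gamma_{fam}[{nm}]" for fam in FAMILIES for nm in des.z_names]
    sigma_names = [f"sigma_eps_{fam}" for fam in FAMILIES]
    Sigma_names = [f"Sigma[{i},{j}]" for i in range(4) for j in range(i, 4)]
    par = {
        nm: np.empty((schedule.chains, R))
        for nm in coef_names + sigma_names + Sigma_names
    }
    session_params = {f: np.empty((schedule.chains, R, S)) for f in FAMILIES}
    theta_store = np.empty((schedule.chains, R, n, 4))
    pointwise = None if prior_only else np.empty((schedule.chains, R, n_points))

    prior_prec = np.eye(p) / _COEF_SD**2

    for chain in range(schedule.chains):
        rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, chain]))

        # initial state
        for attempt in range(_INIT_RETRIES):
            eta = _DEFAULT_LINK_INIT[None, :] + 0.2 * rng.standard_normal((S, 4))
            if prior_only:
                ll = np.zeros(S)
                per: list[np.ndarray | None] = [None] * S
                break
            ll = np.empty(S)
            per = [None] * S
            ok = True
            for s, d in enumerate(designs):
                ll[s], per[s] = _safe_loglik(d, _natural_quadruple(eta[s]))
                ok = ok and np.isfinite(ll[s])
            if ok:
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initial state")
        if not prior_only:
            _check_closed_vs_recursive(data, init, _natural_quadruple(eta[0]))

        coef = np.zeros((4, p))
        coef[:, 0] = eta.mean(axis=0)
        theta = np.zeros((n, 4))
        sigma = np.full(4, 0.5)
        Sigma = np.eye(4)

        eta_steps = _AdaptiveSteps((S, 4))
        sig_steps = _AdaptiveSteps(4, init=0.3)
        coef_steps = _AdaptiveSteps(4, init=0.1)
        theta_steps = _AdaptiveSteps(n, init=0.1)
        sessions_of = [np.flatnonzero(pidx == i) for i in range(n)]

        r = 0
        for it in range(schedule.burnin + schedule.iterations):
            mean = W @ coef.T + theta[pidx]  # (S, 4)

            # 1) session-level link parameters (Metropolis)
            if prior_only:
                prop = eta + eta_steps.step * rng.standard_normal((S, 4))
                logr = (
                    -0.5 * ((prop - mean) ** 2 - (eta - mean) ** 2) / sigma[None, :] ** 2
                )
                acc = np.log(rng.random((S, 4))) < logr
                eta = np.where(acc, prop, eta)
                eta_steps.acc += acc
                eta_steps.tries += 1
            else:
                z_prop = rng.standard_normal((S, 4))
                log_u = np.log(rng.random((S, 4)))
                for s, d in enumerate(designs):
                    for fi in range(4):
                        prop = eta[s].copy()
                        prop[fi] += eta_steps.step[s, fi] * z_prop[s, fi]
                        ll_new, per_new = _safe_loglik(d, _natural_quadruple(prop))
                        logr = (
                            (ll_new - ll[s])
                            - 0.5
                            * ((prop[fi] - mean[s, fi]) ** 2 - (eta[s, fi] - mean[s, fi]) ** 2)
                            / sigma[fi] ** 2
                        )
                        accepted = log_u[s, fi] < logr
                        if accepted:
                            eta[s], ll[s], per[s] = prop, ll_new, per_new
                        eta_steps.record((s, fi), accepted)

            # 2) regression coefficients (conjugate Gibbs per family)
            for fi in range(4):
                resid = eta[:, fi] - theta[pidx, fi]
                prec = WtW / sigma[fi] ** 2 + prior_prec
                chol = np.linalg.cholesky(prec)
                m = np.linalg.solve(prec, W.T @ resid / sigma[fi] ** 2)
                coef[fi] = m + np.linalg.solve(chol.T, rng.standard_normal(p))

            # 3) participant random effects (conjugate Gibbs, joint over families)
            Sigma_inv = np.linalg.inv(Sigma)
            resid = eta - W @ coef.T  # (S, 4)
            rsum = np.zeros((n, 4))
            np.add.at(rsum, pidx, resid)
            if uniform_counts:
                prec = Sigma_inv + np.diag(counts[0] / sigma**2)
                cov = np.linalg.inv(prec)
                Lc = np.linalg.cholesky(cov)
                means = (rsum / sigma[None, :] ** 2) @ cov.T
                theta = means + rng.standard_normal((n, 4)) @ Lc.T
            else:
                for i in range(n):
                    prec = Sigma_inv + np.diag(counts[i] / sigma**2)
                    cov = np.linalg.inv(prec)
                    m = cov @ (rsum[i] / sigma**2)
                    theta[i] = m + np.linalg.cholesky(cov) @ rng.standard_normal(4)

            # 3b) non-centred (ancillarity) coefficient moves: shift a whole
            # coefficient row and every session's link parameter together,
            # holding residuals fixed.  Without them the population level
            # freezes once sigma_eps collapses (the centred Gibbs layer can
            # then no longer move the level against the likelihood).  Every
            # other sweep the intercept instead gets a heavy-tailed (Cauchy)
            # independence proposal centred at the default link values: a
            # mode-hopping kernel whose reverse density decays only
            # polynomially, so the chain can return from (or correctly
            # visit) the saturated-link plateau where the likelihood is
            # flat, instead of random-walking for thousands of sweeps.
            hop_sweep = it % 2 == 1
            for fi in range(4):
                if hop_sweep:
                    c0_new = _DEFAULT_LINK_INIT[fi] + _HOP_SCALE * rng.standard_cauchy()
                    d = np.zeros(p)
                    d[0] = c0_new - coef[fi, 0]
                    log_hastings = _cauchy_logpdf(
                        coef[fi, 0], _DEFAULT_LINK_INIT[fi], _HOP_SCALE
                    ) - _cauchy_logpdf(c0_new, _DEFAULT_LINK_INIT[fi], _HOP_SCALE)
                else:
                    d = coef_steps.step[fi] * rng.standard_normal(p)
                    log_hastings = 0.0
                c_new = coef[fi] + d
                dlp = (
                    -0.5 * float(c_new @ c_new - coef[fi] @ coef[fi]) / _COEF_SD**2
                    + log_hastings
                )
                shift = W @ d
                eta_col = eta[:, fi] + shift
                if prior_only:
                    dll, ll_new, per_new = 0.0, ll, per
                else:
                    eta_prop = eta.copy()
                    eta_prop[:, fi] = eta_col
                    ll_new = np.empty(S)
                    per_new = [None] * S
                    for s, d_ in enumerate(designs):
                        ll_new[s], per_new[s] = _safe_loglik(
                            d_, _natural_quadruple(eta_prop[s])
                        )
                    dll = float(ll_new.sum() - ll.sum())
                accepted = np.log(rng.random()) < dll + dlp
                if accepted:
                    coef[fi] = c_new
                    eta[:, fi] = eta_col
                    ll, per = ll_new, per_new
                if not hop_sweep:
                    coef_steps.record(fi, accepted)

            # joint hop across all four intercepts: modes of different
            # families are mutually tuned (a collapsed delta level pairs
            # with shifted lam/phi/rho levels), so single-family hops jump
            # between modes uphill; the joint proposal gives the
            # well-identified region a fair chance in one move.
            if hop_sweep:
                c0_new = _DEFAULT_LINK_INIT + _HOP_SCALE * rng.standard_cauchy(4)
                d4 = c0_new - coef[:, 0]
                log_hastings = 0.0
                for fi in range(4):
                    log_hastings += _cauchy_logpdf(
                        coef[fi, 0], _DEFAULT_LINK_INIT[fi], _HOP_SCALE
                    ) - _cauchy_logpdf(c0_new[fi], _DEFAULT_LINK_INIT[fi], _HOP_SCALE)
                dlp = log_hastings - 0.5 * float(
                    np.sum((coef[:, 0] + d4) ** 2) - np.sum(coef[:, 0] ** 2)
                ) / _COEF_SD**2
                eta_prop = eta + d4[None, :]
                if prior_only:
                    dll, ll_new, per_new = 0.0, ll, per
                else:
                    ll_new = np.empty(S)
                    per_new = [None] * S
                    for s, d_ in enumerate(designs):
                        ll_new[s], per_new[s] = _safe_loglik(
                            d_, _natural_quadruple(eta_prop[s])
                        )
                    dll = float(ll_new.sum() - ll.sum())
                if np.log(rng.random()) < dll + dlp:
                    coef[:, 0] += d4
                    eta = eta_prop
                    ll, per = ll_new, per_new

            # 3c) non-centred participant move: shift theta_i and the link
            # parameters of participant i's sessions jointly (all families).
            Sigma_inv = np.linalg.inv(Sigma)
            for i in range(n):
                d = theta_steps.step[i] * rng.standard_normal(4)
                th_new = theta[i] + d
                dlp = -0.5 * float(th_new @ Sigma_inv @ th_new - theta[i] @ Sigma_inv @ theta[i])
                sess = sessions_of[i]
                if prior_only:
                    dll = 0.0
                    new_vals = []
                else:
                    dll = 0.0
                    new_vals = []
                    for s in sess:
                        lls, pers = _safe_loglik(
                            designs[s], _natural_quadruple(eta[s] + d)
                        )
                        new_vals.append((s, lls, pers))
                        dll += lls - ll[s]
                accepted = np.log(rng.random()) < dll + dlp
                if accepted:
                    theta[i] = th_new
                    eta[sess] += d
                    for s, lls, pers in new_vals:
                        ll[s], per[s] = lls, pers
                theta_steps.record(i, accepted)

            # 4) residual scales: RW Metropolis on log sigma (residuals fixed)
            eps = eta - W @ coef.T - theta[pidx]
            for fi in range(4):
                u_cur = np.log(sigma[fi])
                u_new = u_cur + sig_steps.step[fi] * rng.standard_normal()
                s_new = np.exp(u_new)
                if s_new < _SIGMA_UPPER:
                    ss = float(np.sum(eps[:, fi] ** 2))
                    logr = (
                        -S * (u_new - u_cur)
                        - 0.5 * ss * (1.0 / s_new**2 - 1.0 / sigma[fi] ** 2)
                        + (u_new - u_cur)  # log-scale Jacobian of the uniform prior
                    )
                    accepted = np.log(rng.random()) < logr
                else:
                    accepted = False
                if accepted:
                    sigma[fi] = s_new
                sig_steps.record(fi, accepted)

            # 4b) joint (sigma, residual) rescaling moves: multiply the
            # session residuals by sigma'/sigma so the scale hierarchy can
            # traverse the Uniform(0, 1000) prior range.  Two proposals: a
            # log-scale random walk (posterior scale mixing) and a uniform
            # independence draw (exact prior traversal); both leave the
            # target invariant and reduce to acceptance-by-likelihood-ratio.
            if prior_only or (it + 1) % _RESCALE_EVERY == 0:
                mean = W @ coef.T + theta[pidx]
                # The uniform independence proposal traverses the prior
                # exactly but, against a likelihood, manufactures transient
                # huge-sigma states that seed the saturation plateau; it is
                # used only when the likelihood is disabled.
                kinds = ("rw", "indep") if prior_only else ("rw",)
                for kind in kinds:
                    for fi in range(4):
                        if kind == "rw":
                            jump = 0.7 * rng.standard_normal()
                            s_new = sigma[fi] * np.exp(jump)
                            log_hastings = jump  # d sigma / d log sigma
                        else:
                            s_new = _SIGMA_UPPER * rng.random()
                            log_hastings = 0.0
                        if s_new >= _SIGMA_UPPER:
                            continue
                        scale = s_new / sigma[fi]
                        eta_new = eta.copy()
                        eta_new[:, fi] = mean[:, fi] + scale * (eta[:, fi] - mean[:, fi])
                        if prior_only:
                            dll = 0.0
                            ll_new, per_new = ll, per
                        else:
                            ll_new = np.empty(S)
                            per_new = [None] * S
                            for s, d in enumerate(designs):
                                ll_new[s], per_new[s] = _safe_loglik(
                                    d, _natural_quadruple(eta_new[s])
                                )
                            dll = float(ll_new.sum() - ll.sum())
                        logr = dll + log_hastings
                        if np.log(rng.random()) < logr:
                            sigma[fi] = s_new
                            eta = eta_new
                            ll, per = ll_new, per_new

            # 5) random-effect covariance (conjugate inverse-Wishart)
            scale_post = np.linalg.inv(np.eye(4) + theta.T @ theta)
            prec = stats.wishart.rvs(df=_WISHART_DF + n, scale=scale_post, random_state=rng)
            Sigma = np.linalg.inv(prec)

            if it < schedule.burnin:
                if (it + 1) % _ADAPT_WINDOW == 0:
                    eta_steps.adapt()
                    sig_steps.adapt()
                    coef_steps.adapt()
                    theta_steps.adapt()
            elif (it - schedule.burnin + 1) % schedule.thin == 0:
                for fi, fam in enumerate(FAMILIES):
                    for j in range(p_x):
                        par[f"beta_{fam}[{des.x_names[j]}]"][chain, r] = coef[fi, j]
                for fi, fam in enumerate(FAMILIES):
                    for j in range(p_z):
                        par[f"gamma_{fam}[{des.z_names[j]}]"][chain, r] = coef[fi, p_x + j]
                for fi, fam in enumerate(FAMILIES):
                    par[f"sigma_eps_{fam}"][chain, r] = sigma[fi]
                for i in range(4):
                    for j in range(i, 4):
                        par[f"Sigma[{i},{j}]"][chain, r] = Sigma[i, j]
                theta_store[chain, r] = theta
                for s in range(S):
                    nat = _natural_quadruple(eta[s])
                    for fi, fam in enumerate(FAMILIES):
                        session_params[fam][chain, r, s] = nat[fi]
                    if not prior_only:
                        pointwise[chain, r, offsets[s]: offsets[s + 1]] = per[s]
                r += 1
        assert r == R

    ps = PosteriorSamples(
        model="full",
        schedule=schedule,
        params=par,
        session_params=session_params,
        session_keys=data.session_keys,
        pointwise=pointwise,
        point_index=None if prior_only else _point_index(data),
    )
    ps.theta = theta_store  # (chains, retained, participants, families)
    return ps


def sigma_matrix_draws(ps: PosteriorSamples) -> np.ndarray:
    """Assemble full Sigma draws, shape (total draws, 4, 4)."""
    out = np.empty((ps.n_retained, 4, 4))
    for i in range(4):
        for j in range(i, 4):
            x = ps.flat(f"Sigma[{i},{j}]")
            out[:, i, j] = x
            out[:, j, i] = x
    return out
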