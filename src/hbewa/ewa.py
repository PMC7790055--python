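"""Experience-weighted attraction (EWA) learning.

The EWA model assigns each strategy ``k`` a latent attraction
``V_k(t)`` updated after every round, together with a scalar experience
weight ``N(t)`` counting observation-equivalents of past play:

    N(t)   = rho * N(t-1) + 1
    V_k(t) = [ phi * N(t-1) * V_k(t-1) + f_k(t) ] / N(t)
    f_k(t) = { delta + (1 - delta) * I(Y(t) = k) } * pi(k, Y*(t))

where ``Y(t)`` is the own choice, ``Y*(t)`` the opponent's, and ``pi`` the
game payoff.  ``delta`` interpolates between pure reinforcement learning
(delta = 0: only the chosen strategy's realised payoff reinforces) and pure
belief learning / fictitious play (delta = 1: all strategies are updated by
their foregone payoffs).  ``phi`` decays previous attractions, ``rho``
decays the experience weight.  Choice probabilities are softmax in the
attractions with sensitivity ``lambda``:

    p_k(t) = exp(lam * V_k(t-1)) / sum_l exp(lam * V_l(t-1))

Both recursive updates and the algebraically equivalent closed forms

    N(t) = rho^t N(0) + (1 - rho^t) / (1 - rho)
    V_k(t) = [ phi^t V_k(0) N(0) + sum_{l=1..t} f_k(l) phi^(t-l) ] / N(t)

are implemented; the closed forms (vectorised over rounds) are the fast
path used inside the samplers, the recursion serves as an independent
oracle in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .game import GameSpec

#: Canonical ordering of the four EWA parameter families.
FAMILIES = ("delta", "lam", "phi", "rho")

_RHO_ONE_TOL = 1e-12

try:  # numba accelerates the innermost sampler loop ~10x when present
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _per_round_logp_jit(P, onehot, choice_idx, v0, n0, delta, lam, phi, rho):
    # Closed-form evaluation: V(t) = (phi^t V0 N0 + S(t)) / N(t) with the
    # convolution sum S(t) = sum_l f(l) phi^(t-l) accumulated as a running
    # recurrence and N(t) from its closed form.
    g, K = P.shape
    out = np.empty(g)
    S = np.zeros(K)
    V = v0.copy()  # V(t-1), drives the round-t choice
    phit = 1.0
    rhot = 1.0
    rho_is_one = abs(1.0 - rho) < 1e-12
    for t in range(1, g + 1):
        m = lam * V[0]
        for k in range(1, K):
            z = lam * V[k]
            if z > m:
                m = z
        tot = 0.0
        for k in range(K):
            tot += np.exp(lam * V[k] - m)
        out[t - 1] = lam * V[choice_idx[t - 1]] - m - np.log(tot)

        phit *= phi
        if rho_is_one:
            N = n0 + t
        else:
            rhot *= rho
            N = rhot * n0 + (1.0 - rhot) / (1.0 - rho)
        for k in range(K):
            f = (delta + (1.0 - delta) * onehot[t - 1, k]) * P[t - 1, k]
            S[k] = phi * S[k] + f
            V[k] = (phit * v0[k] * n0 + S[k]) / N
    return out


@dataclass(frozen=True)
class EWAParams:
    """The EWA parameter quadruple for one participant-session.

    Supports: ``delta, phi, rho`` in [0, 1] and ``lam >= 0``.  The closed
    unit-interval limits (pure reinforcement/belief learning, no decay,
    full decay) are meaningful and implemented; the hierarchical link
    functions keep parameters strictly interior when these values arise
    from the regression model.
    """

    delta: float
    lam: float
    phi: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("delta", "phi", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.lam >= 0.0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.lam, self.phi, self.rho])

    @classmethod
    def from_array(cls, a) -> "EWAParams":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class AttractionState:
    """Attractions, experience weight and round index after round ``t``."""

    V: np.ndarray
    N: float
    t: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float))
        if self.N <= 0:
            raise ValueError(f"experience weight must be positive, got {self.N}")


@dataclass
class SessionData:
    """One participant-session's observed play.

    ``choices[t-1]`` and ``opponent_choices[t-1]`` are the round-``t``
    investments (rounds are 1-based).  ``start`` is the first round whose
    choice contributes to the likelihood; attractions still evolve through
    the earlier rounds, so the round-``start`` probabilities reflect the
    full history.
    """

    participant: str
    session: int
    role: int
    choices: np.ndarray
    opponent_choices: np.ndarray
    start: int = 6

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.opponent_choices = np.asarray(self.opponent_choices, dtype=int)
        if self.choices.shape != self.opponent_choices.shape:
            raise ValueError(
                f"choice sequences have mismatched lengths "
                f"{len(self.choices)} vs {len(self.opponent_choices)}"
            )
        if self.start < 1:
            raise ValueError(f"likelihood start round must be >= 1, got {self.start}")

    @property
    def n_rounds(self) -> int:
        return len(self.choices)

    def validate(self, game: GameSpec) -> None:
        own_max = game.endowment(self.role)
        opp_max = game.endowment(game.opposing(self.role))
        for t, (c, o) in enumerate(zip(self.choices, self.opponent_choices), start=1):
            if not 0 <= c <= own_max:
                raise ValueError(
                    f"round {t}: choice {c} outside action space 0..{own_max} "
                    f"(participant {self.participant}, session {self.session})"
                )
            if not 0 <= o <= opp_max:
                raise ValueError(
                    f"round {t}: opponent choice {o} outside action space 0..{opp_max} "
                    f"(participant {self.participant}, session {self.session})"
                )


# ---------------------------------------------------------------------------
# recursive updates (reference path / oracle)
# ---------------------------------------------------------------------------

def update_state(
    state: AttractionState,
    params: EWAParams,
    own_choice: int,
    opponent_choice: int,
    game: GameSpec,
    role: int,
) -> AttractionState:
    """One round of the EWA recursion, returning the state after round t+1."""
    K = game.n_actions(role)
    if len(state.V) != K:
        raise ValueError(f"attraction vector length {len(state.V)} != {K} actions")
    t = state.t + 1
    if not 0 <= own_choice < K:
        raise ValueError(f"round {t}: invalid choice {own_choice} for role {role}")
    opp_max = game.endowment(game.opposing(role))
    if not 0 <= opponent_choice <= opp_max:
        raise ValueError(f"round {t}: invalid opponent choice {opponent_choice}")

    pi = game.payoff_matrix(role)[:, opponent_choice]
    indicator = np.zeros(K)
    indicator[own_choice] = 1.0
    f = (params.delta + (1.0 - params.delta) * indicator) * pi
    n_new = params.rho * state.N + 1.0
    v_new = (params.phi * state.N * state.V + f) / n_new
    return AttractionState(V=v_new, N=n_new, t=t)


def experience_weight_closed(rho: float, n0: float, t: int) -> float:
    """Closed form ``N(t) = rho^t N(0) + (1 - rho^t)/(1 - rho)``.

    At ``rho = 1`` the limit ``N(0) + t`` is returned.
    """
    if t < 0:
        raise ValueError(f"round index must be >= 0, got {t}")
    if abs(1.0 - rho) < _RHO_ONE_TOL:
        return float(n0 + t)
    rt = rho**t
    return float(rt * n0 + (1.0 - rt) / (1.0 - rho))


def reinforcements(
    delta: float,
    choices: np.ndarray,
    opponent_choices: np.ndarray,
    game: GameSpec,
    role: int,
) -> np.ndarray:
    """Reinforcement terms ``f_k(t)`` for all rounds; shape (g, K)."""
    pi = game.payoff_matrix(role)
    P = pi[:, np.asarray(opponent_choices, dtype=int)].T  # (g, K)
    onehot = np.zeros_like(P)
    onehot[np.arange(len(choices)), np.asarray(choices, dtype=int)] = 1.0
    return (delta + (1.0 - delta) * onehot) * P


def attractions_closed(
    params: EWAParams,
    v0: np.ndarray,
    n0: float,
    choices: np.ndarray,
    opponent_choices: np.ndarray,
    t: int,
    game: GameSpec,
    role: int,
) -> np.ndarray:
    """Attraction vector after round ``t`` via the closed form."""
    choices = np.asarray(choices, dtype=int)
    opponent_choices = np.asarray(opponent_choices, dtype=int)
    if choices.shape != opponent_choices.shape:
        raise ValueError("choice and opponent sequences have mismatched lengths")
    if not 0 <= t <= len(choices):
        raise ValueError(f"round {t} outside observed sequence of length {len(choices)}")
    v0 = np.asarray(v0, dtype=float)
    if t == 0:
        return v0.copy()
    f = reinforcements(params.delta, choices[:t], opponent_choices[:t], game, role)
    powers = params.phi ** np.arange(t - 1, -1, -1.0)
    num = (params.phi**t) * v0 * n0 + powers @ f
    return num / experience_weight_closed(params.rho, n0, t)


def choice_probabilities(state, lam: float, game: GameSpec, role: int) -> np.ndarray:
    """Softmax choice probabilities from attractions (max-subtracted)."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    V = state.V if isinstance(state, AttractionState) else np.asarray(state, dtype=float)
    if len(V) != game.n_actions(role):
        raise ValueError(
            f"attraction vector length {len(V)} does not match the "
            f"{game.n_actions(role)} actions of role {role}"
        )
    z = lam * V
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# fast closed-form session likelihood
# ---------------------------------------------------------------------------

class SessionDesign:
    """Precomputed per-session arrays for fast likelihood evaluation.

    Holds the payoff columns ``P[t, k] = pi(k, Y*(t))``, the one-hot own
    choices, and the initial conditions; :meth:`log_likelihood` then costs
    a handful of vectorised operations per call, which is what makes
    Metropolis sampling over thousands of iterations affordable.
    """

    __slots__ = (
        "data", "P", "onehot", "choice_idx", "start_idx", "v0", "n0", "g", "K", "tt",
    )

    def __init__(self, data: SessionData, game: GameSpec, v0: np.ndarray, n0: float = 1.0):
        data.validate(game)
        self.data = data
        self.g = data.n_rounds
        self.K = game.n_actions(data.role)
        self.v0 = np.asarray(v0, dtype=float)
        if len(self.v0) != self.K:
            raise ValueError(f"v0 length {len(self.v0)} != {self.K} actions")
        self.n0 = float(n0)
        pi = game.payoff_matrix(data.role)
        self.P = pi[:, data.opponent_choices].T  # (g, K)
        self.choice_idx = data.choices
        self.onehot = np.zeros((self.g, self.K))
        self.onehot[np.arange(self.g), self.choice_idx] = 1.0
        self.start_idx = data.start - 1  # 0-based first likelihood round
        if self.start_idx >= self.g:
            raise ValueError(
                f"likelihood start round {data.start} beyond session length {self.g}"
            )
        self.tt = np.arange(1.0, self.g + 1.0)

    @property
    def n_points(self) -> int:
        return self.g - self.start_idx

    def per_round_logp(self, delta: float, lam: float, phi: float, rho: float) -> np.ndarray:
        """Log choice probabilities for every round 1..g (full history)."""
        if _HAVE_NUMBA:
            return _per_round_logp_jit(
                self.P, self.onehot, self.choice_idx, self.v0, self.n0,
                float(delta), float(lam), float(phi), float(rho),
            )
        return self._per_round_logp_numpy(delta, lam, phi, rho)

    def _per_round_logp_numpy(self, delta, lam, phi, rho) -> np.ndarray:
        f = self.P * (delta + (1.0 - delta) * self.onehot)
        S = lfilter([1.0], [1.0, -phi], f, axis=0)  # S(t) = phi S(t-1) + f(t)
        if abs(1.0 - rho) < _RHO_ONE_TOL:
            N = self.n0 + self.tt
        else:
            rt = rho**self.tt
            N = rt * self.n0 + (1.0 - rt) / (1.0 - rho)
        V = ((phi**self.tt)[:, None] * (self.v0 * self.n0) + S) / N[:, None]
        Vprev = np.concatenate([self.v0[None, :], V[:-1]], axis=0)
        with np.errstate(invalid="ignore", over="ignore"):
            logits = lam * Vprev
            m = logits.max(axis=1)
            lse = m + np.log(np.exp(logits - m[:, None]).sum(axis=1))
            return logits[np.arange(self.g), self.choice_idx] - lse

    def log_likelihood(self, delta, lam, phi, rho) -> tuple[float, np.ndarray]:
        """Total log-likelihood and per-round log-probabilities.

        The per-round vector covers only rounds >= the likelihood start;
        earlier rounds evolve the state but do not contribute.
        """
        logp = self.per_round_logp(delta, lam, phi, rho)[self.start_idx:]
        with np.errstate(over="ignore"):
            return float(logp.sum()), logp


def session_log_likelihood(
    data: SessionData,
    params: EWAParams,
    v0: np.ndarray,
    n0: float,
    game: GameSpec,
    method: str = "closed",
) -> tuple[float, np.ndarray]:
    """Categorical log-likelihood of one session and its per-round terms.

    ``method="closed"`` uses the vectorised closed forms;
    ``method="recursive"`` replays the state update round by round.  The
    two agree to floating tolerance and the recursive path is kept as an
    independent oracle.
    """
    if method == "closed":
        design = SessionDesign(data, game, v0, n0)
        total, logp = design.log_likelihood(params.delta, params.lam, params.phi, params.rho)
    elif method == "recursive":
        data.validate(game)
        state = AttractionState(V=np.asarray(v0, dtype=float), N=n0, t=0)
        logps = []
        for t in range(1, data.n_rounds + 1):
            p = choice_probabilities(state, params.lam, game, data.role)
            if t >= data.start:
                logps.append(np.log(p[data.choices[t - 1]]))
            state = update_state(
                state, params, data.choices[t - 1], data.opponent_choices[t - 1],
                game, data.role,
            )
        logp = np.array(logps)
        total = float(logp.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(total):
        warnings.warn(
            f"log-likelihood numerically -inf for participant {data.participant} "
            f"session {data.session}",
            RuntimeWarning,
        )
        return -np.inf, logp
    return total, logp


class StackedSessions:
    """Role-grouped stack of sessions sharing one parameter quadruple.

    Used by the shared-parameter sampler: with identical ``phi`` across
    sessions the attraction filter runs once over a (sessions, rounds,
    actions) block per role, which is an order of magnitude faster than
    looping sessions.
    """

    def __init__(self, designs: list[SessionDesign]):
        self.designs = designs
        self._groups: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float,
                                 np.ndarray, int, list[int]]] = []
        by_k: dict[int, list[int]] = {}
        for i, d in enumerate(designs):
            by_k.setdefault(d.K, []).append(i)
        for K, idx in by_k.items():
            g = {designs[i].g for i in idx}
            if len(g) > 1:
                raise ValueError("stacked sessions must share the round count")
            g = g.pop()
            P = np.stack([designs[i].P for i in idx])          # (S, g, K)
            onehot = np.stack([designs[i].onehot for i in idx])
            cidx = np.stack([designs[i].choice_idx for i in idx])
            v0 = np.stack([designs[i].v0 for i in idx])        # (S, K)
            n0 = designs[idx[0]].n0
            tt = np.arange(1.0, g + 1.0)
            start = designs[idx[0]].start_idx
            if any(designs[i].start_idx != start for i in idx):
                raise ValueError("stacked sessions must share the likelihood start")
            self._groups.append((P, onehot, cidx, v0, n0, tt, start, idx))

    def log_likelihood(self, delta, lam, phi, rho) -> tuple[float, list[np.ndarray]]:
        """Total log-likelihood and per-round terms per session (design order)."""
        per_session: list[np.ndarray | None] = [None] * len(self.designs)
        total = 0.0
        for P, onehot, cidx, v0, n0, tt, start, idx in self._groups:
            f = P * (delta + (1.0 - delta) * onehot)
            S = lfilter([1.0], [1.0, -phi], f, axis=1)
            if abs(1.0 - rho) < _RHO_ONE_TOL:
                N = n0 + tt
            else:
                rt = rho**tt
                N = rt * n0 + (1.0 - rt) / (1.0 - rho)
            V = ((phi**tt)[None, :, None] * (v0 * n0)[:, None, :] + S) / N[None, :, None]
            Vprev = np.concatenate([v0[:, None, :], V[:, :-1]], axis=1)
            with np.errstate(invalid="ignore", over="ignore"):
                logits = lam * Vprev
                m = logits.max(axis=2)
                lse = m + np.log(np.exp(logits - m[:, :, None]).sum(axis=2))
            g = P.shape[1]
            rows = np.arange(g)[None, :].repeat(len(idx), axis=0)
            sess = np.arange(len(idx))[:, None].repeat(g, axis=1)
            logp = logits[sess, rows, cidx] - lse
            for j, i in enumerate(idx):
                per_session[i] = logp[j, start:]
                total += float(per_session[i].sum())
        return total, per_session  # type: ignore[return-value]
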