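"""Game-play simulator with known ground truth.

Generates long-format datasets from the EWA choice process under two
study designs mirroring the simulation study this package evaluates
itself on:

* ``variability=False`` — a single shared parameter quadruple generates
  every participant-session (four unknowns in total);
* ``variability=True`` — each participant-session receives its own
  quadruple drawn from the hierarchical regression model (covariate
  effects, correlated participant random effects, session residuals).

Opponents default to an exogenous categorical pool (the experimental
protocol this emulates matched participants against pre-recorded
opponents round by round), with an EWA self-play mode as an alternative.
Every dataset is reproducible byte-for-byte from its scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import hierarchy
from .ewa import FAMILIES, AttractionState, EWAParams, choice_probabilities, update_state
from .game import PATENT_RACE, STRONG, WEAK, GameSpec
from .initial import InitialConditions

#: Shared-parameter ground truth: moderate belief-learning weight, slow
#: attraction decay, and a payoff sensitivity that keeps play decisive but
#: stochastic.  With attractions on the payoff scale (roughly -1..14
#: units), lam = 0.6 yields maximum-attraction choice rates around
#: 70-80%, the behaviour of trained, incentivised players.  The
#: sensitivity is the critical dial: much larger values make simulated
#: choices deterministic (lam unidentified from above), while much
#: smaller values make choices so noisy that the reinforcement-vs-belief
#: weight delta is barely identified.  phi and rho sit high and close
#: together (phi ~ rho keeps attractions bounded by the game's payoffs,
#: and fitted investment-game play shows the two decays nearly perfectly
#: correlated); rho near 0.9 also keeps the experience-weight transient
#: alive through the likelihood window — once N(t) reaches its steady
#: state only the product lam*(1-rho) is identified, so smaller rho
#: values are estimable in principle but not in practice.
DEFAULT_SHARED_TRUTH = EWAParams(delta=0.35, lam=0.6, phi=0.90, rho=0.88)

#: Exogenous opponent pools: investment distribution of the *opponent*
#: playing the given role.  Mass concentrates at zero (drop out) and at
#: the top of the endowment (all-in), as observed in Patent Race play.
DEFAULT_OPPONENT_POOL = {
    WEAK: np.array([0.35, 0.10, 0.10, 0.15, 0.30]),
    STRONG: np.array([0.30, 0.05, 0.05, 0.10, 0.15, 0.35]),
}

#: Block-wise opponent pools (one distribution per quarter of the
#: session): pre-recorded human pools are not stationary — early play is
#: exploratory and spread over mid-range investments, later play
#: polarises toward dropping out or going all-in as the pool
#: equilibrates.  The drift matters beyond realism: shifts in opponent
#: behaviour are what separate belief learning (which updates foregone
#: payoffs immediately when the opponent changes) from reinforcement
#: learning (which only learns through own realised payoffs), so a
#: stationary pool leaves the delta parameter nearly unidentified.
DEFAULT_OPPONENT_BLOCKS = {
    WEAK: np.array(
        [
            [0.20, 0.20, 0.20, 0.20, 0.20],
            [0.30, 0.12, 0.10, 0.15, 0.33],
            [0.40, 0.07, 0.06, 0.12, 0.35],
            [0.45, 0.05, 0.05, 0.10, 0.35],
        ]
    ),
    STRONG: np.array(
        [
            [0.17, 0.16, 0.16, 0.17, 0.17, 0.17],
            [0.25, 0.10, 0.08, 0.10, 0.15, 0.32],
            [0.33, 0.06, 0.05, 0.08, 0.12, 0.36],
            [0.38, 0.04, 0.04, 0.06, 0.10, 0.38],
        ]
    ),
}


def greedy_prior_attractions(game: GameSpec, scale: float = 0.5) -> dict[int, np.ndarray]:
    """Initial attractions from pre-game reasoning, per role.

    Players do not start a session indifferent: instructed participants
    reason about payoffs before round 1.  The default initial attraction
    of strategy k is ``scale`` times its expected payoff against a
    uniformly mixing opponent, mean-centred.  Beyond realism this matters
    for identification: the decay of a non-trivial V(0) through the
    growing experience weight N(t) is the main channel through which rho
    is separately identified from lam once the steady state is reached.
    """
    out = {}
    for role in (WEAK, STRONG):
        v = scale * game.payoff_matrix(role).mean(axis=1)
        out[role] = v - v.mean()
    return out

#: Cross-family random-effect correlation: phi and rho nearly collinear,
#: both strongly negatively correlated with delta, lam nearly independent.
DEFAULT_CORRELATION = np.array(
    [
        [1.00, -0.09, -0.65, -0.68],
        [-0.09, 1.00, 0.07, 0.16],
        [-0.65, 0.07, 1.00, 0.97],
        [-0.68, 0.16, 0.97, 1.00],
    ]
)


def _default_sigma() -> np.ndarray:
    sds = np.array([0.5, 0.25, 0.5, 0.5])
    return DEFAULT_CORRELATION * np.outer(sds, sds)


@dataclass(frozen=True)
class HierTruth:
    """Hyperparameter truth for the variability scenario (link scale).

    Defaults: intercepts at the link of the shared truth; small per-year
    age slopes; moderate sex contrasts; role contrasts with the strong
    role more belief-driven (higher delta) but less payoff-sensitive and
    faster-forgetting (lower lam, phi, rho); mild session-1 contrasts.
    """

    intercepts: tuple[float, ...] = tuple(
        hierarchy.link(getattr(DEFAULT_SHARED_TRUTH, f), f) for f in FAMILIES
    )
    beta_age: tuple[float, ...] = (-0.02, 0.01, 0.02, 0.02)
    beta_sex: tuple[float, ...] = (0.30, -0.06, 0.50, 0.45)
    gamma_role: tuple[float, ...] = (1.54, -0.69, -1.35, -1.20)
    gamma_session: tuple[float, ...] = (0.14, 0.15, -0.43, -0.27)
    sigma_eps: tuple[float, ...] = (0.25, 0.15, 0.25, 0.25)
    Sigma: np.ndarray = field(default_factory=_default_sigma)

    def beta(self) -> np.ndarray:
        return np.column_stack([self.intercepts, self.beta_age, self.beta_sex])

    def gamma(self) -> np.ndarray:
        return np.column_stack([self.gamma_role, self.gamma_session])


@dataclass(frozen=True)
class SimScenario:
    """Design of one simulated study."""

    n_participants: int = 42
    n_sessions: int = 2
    n_rounds: int = 80
    variability: bool = False
    truth: EWAParams = DEFAULT_SHARED_TRUTH
    hier_truth: HierTruth = field(default_factory=HierTruth)
    opponent_mode: str = "pool"  # "pool" or "selfplay"
    opponent_pool: dict | None = None
    initial_conditions: InitialConditions | None = None
    likelihood_start: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_sessions, self.n_rounds) < 1:
            raise ValueError("n_participants, n_sessions and n_rounds must all be >= 1")
        if self.opponent_mode not in ("pool", "selfplay"):
            raise ValueError(f"unknown opponent mode {self.opponent_mode!r}")
        if self.opponent_pool is not None:
            for role, p in self.opponent_pool.items():
                p = np.atleast_2d(np.asarray(p, dtype=float))
                if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
                    raise ValueError(f"opponent pool for role {role} is not a distribution")


def simulate_opponents(
    mode: str,
    g: int,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Opponent investment sequence of length g for the exogenous pool mode.

    ``pool`` is either a single probability vector (stationary pool) or a
    (blocks, actions) array of per-round-block distributions spread evenly
    over the session.
    """
    if mode != "pool":
        raise ValueError("simulate_opponents handles the exogenous pool mode only")
    p = np.atleast_2d(np.asarray(pool, dtype=float))
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("opponent pool must be a probability vector per block")
    n_blocks = p.shape[0]
    edges = np.linspace(0, g, n_blocks + 1).astype(int)
    out = np.empty(g, dtype=int)
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        if hi > lo:
            out[lo:hi] = rng.choice(p.shape[1], size=hi - lo, p=p[b])
    return out


def _draw_session_params(
    ht: HierTruth,
    x: np.ndarray,
    z: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> EWAParams:
    vals = {}
    beta, gamma = ht.beta(), ht.gamma()
    for fi, fam in enumerate(FAMILIES):
        eps = rng.normal(0.0, ht.sigma_eps[fi])
        vals[fam] = hierarchy.parameter_from_linear_predictor(
            x, z, beta[fi], gamma[fi], theta[fi], eps, fam
        )
    return EWAParams(**vals)


def _play_session(
    params: EWAParams,
    role: int,
    opp_seq: np.ndarray,
    v0: np.ndarray,
    n0: float,
    game: GameSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    g = len(opp_seq)
    state = AttractionState(V=v0, N=n0, t=0)
    choices = np.empty(g, dtype=int)
    for t in range(g):
        p = choice_probabilities(state, params.lam, game, role)
        choices[t] = rng.choice(len(p), p=p)
        state = update_state(state, params, choices[t], opp_seq[t], game, role)
    return choices


def _play_selfplay(
    params: EWAParams,
    opp_params: EWAParams,
    role: int,
    g: int,
    v0: np.ndarray,
    v0_opp: np.ndarray,
    n0: float,
    game: GameSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    opp_role = game.opposing(role)
    state = AttractionState(V=v0, N=n0, t=0)
    opp_state = AttractionState(V=v0_opp, N=n0, t=0)
    own = np.empty(g, dtype=int)
    opp = np.empty(g, dtype=int)
    for t in range(g):
        p = choice_probabilities(state, params.lam, game, role)
        q = choice_probabilities(opp_state, opp_params.lam, game, opp_role)
        own[t] = rng.choice(len(p), p=p)
        opp[t] = rng.choice(len(q), p=q)
        state = update_state(state, params, own[t], opp[t], game, role)
        opp_state = update_state(opp_state, opp_params, opp[t], own[t], game, opp_role)
    return own, opp


def simulate_dataset(
    scenario: SimScenario,
    game: GameSpec = PATENT_RACE,
) -> tuple[pd.DataFrame, pd.DataFrame, InitialConditions]:
    """Simulate a full study.

    Returns the long-format data table (participant, session, round, role,
    choice, opponent_choice, age, sex), the ground-truth parameter table
    keyed by (participant, session, family), and the initial conditions
    used to generate play (payoff-reasoned greedy prior attractions,
    N(0) = 1).
    """
    rng = np.random.default_rng(scenario.seed)
    ht = scenario.hier_truth
    pool = scenario.opponent_pool or DEFAULT_OPPONENT_BLOCKS

    n, s, g = scenario.n_participants, scenario.n_sessions, scenario.n_rounds
    ages = np.clip(np.round(rng.normal(22.3, 5.9, size=n)), 18, 47).astype(int)
    sexes = (rng.random(n) < 1.0 / 3.0).astype(int)  # 1 = male
    age_c = ages - ages.mean()
    thetas = (
        hierarchy.sample_random_effects(ht.Sigma, n, rng)
        if scenario.variability
        else np.zeros((n, 4))
    )

    prior_v0 = greedy_prior_attractions(game)
    init = scenario.initial_conditions or InitialConditions(
        v0={
            (sess, role): prior_v0[role]
            for sess in range(1, s + 1)
            for role in (WEAK, STRONG)
        },
        n0=1.0,
    )

    rows, truth_rows = [], []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        for sess in range(1, s + 1):
            # roles alternate across participants and swap between sessions
            role = (i + sess + 1) % 2
            if scenario.variability:
                x = np.array([1.0, age_c[i], float(sexes[i])])
                z = np.array([float(role), float(sess == 1)])
                params = _draw_session_params(ht, x, z, thetas[i], rng)
            else:
                params = scenario.truth
            v0 = init.for_session(sess, role)
            if scenario.opponent_mode == "pool":
                opp_role = game.opposing(role)
                opp_seq = simulate_opponents("pool", g, rng, pool[opp_role])
                choices = _play_session(params, role, opp_seq, v0, init.n0, game, rng)
            else:
                v0_opp = init.for_session(sess, game.opposing(role))
                choices, opp_seq = _play_selfplay(
                    params, scenario.truth, role, g, v0, v0_opp, init.n0, game, rng
                )
            for t in range(g):
                rows.append(
                    (pid, sess, t + 1, role, choices[t], opp_seq[t], ages[i], sexes[i])
                )
            for fam in FAMILIES:
                truth_rows.append((pid, sess, fam, getattr(params, fam)))

    data = pd.DataFrame(
        rows,
        columns=[
            "participant", "session", "round", "role",
            "choice", "opponent_choice", "age", "sex",
        ],
    )
    truth = pd.DataFrame(truth_rows, columns=["participant", "session", "family", "value"])
    return data, truth, init
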