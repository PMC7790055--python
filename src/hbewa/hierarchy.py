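"""Parameter-level regression models, random effects and priors.

Each EWA parameter family f in {delta, lam, phi, rho} is modelled on a
link scale with a linear predictor combining participant covariates,
session covariates, a correlated participant random effect and a session
residual:

    q_f(param_ij) = x_i' beta_f + z_ij' gamma_f + theta_i_f + eps_ij_f
    eps_ij_f ~ N(0, sigma_f^2),   theta_i ~ MVN(0_4, Sigma)

with logit links for delta, phi, rho and the natural log for lam.  The
4x4 covariance Sigma captures cross-correlation between a participant's
four parameter families across sessions.

Priors: every beta and gamma component N(0, 100^2); each residual scale
sigma_f Uniform(0, 1000); Sigma^{-1} Wishart with identity scale and 5
degrees of freedom — for a 4x4 matrix, df = dimension + 1 makes the
implied prior correlations marginally uniform on (-1, 1).

Covariate coding: age enters mean-centred (per year), sex as 1 = male,
role as 1 = strong, session as 1 = session 1 (so the session coefficient
is the session-1-vs-2 contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewa import FAMILIES

_LOGIT_FAMILIES = ("delta", "phi", "rho")

#: Default prior hyperparameters.
BETA_PRIOR_SD = 100.0
SIGMA_EPS_UPPER = 1000.0
WISHART_DF = 5


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown parameter family {family!r}; expected one of {FAMILIES}")
    return family


def link(value: float, family: str) -> float:
    """Map a parameter value to the real line (logit, or log for lam)."""
    _check_family(family)
    value = float(value)
    if family == "lam":
        if value <= 0:
            raise ValueError(f"lam must be > 0 to link, got {value}")
        return float(np.log(value))
    if not 0.0 < value < 1.0:
        raise ValueError(f"{family} must lie in (0, 1) to link, got {value}")
    return float(np.log(value) - np.log1p(-value))


def inverse_link(x: float, family: str) -> float:
    """Inverse of :func:`link`; always inside the family support."""
    _check_family(family)
    x = float(x)
    with np.errstate(over="ignore"):
        if family == "lam":
            return float(np.exp(x))
        return float(1.0 / (1.0 + np.exp(-x)))


def parameter_from_linear_predictor(
    x: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    theta: float,
    eps: float,
    family: str,
) -> float:
    """EWA parameter implied by the link-scale regression terms."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if x.shape != beta.shape:
        raise ValueError(f"x has shape {x.shape} but beta has shape {beta.shape}")
    if z.shape != gamma.shape:
        raise ValueError(f"z has shape {z.shape} but gamma has shape {gamma.shape}")
    eta = float(x @ beta + z @ gamma + theta + eps)
    return inverse_link(eta, family)


def sample_random_effects(Sigma: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n iid MVN(0, Sigma) participant random effects; shape (n, 4)."""
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (4, 4):
        raise ValueError(f"Sigma must be 4x4, got shape {Sigma.shape}")
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma must be positive definite") from exc
    return rng.standard_normal((n, 4)) @ L.T


@dataclass
class HierParams:
    """All hierarchical unknowns: regression coefficients per family,
    residual scales, random-effect covariance, and participant effects."""

    beta: np.ndarray       # (4, p_x), family-major in FAMILIES order
    gamma: np.ndarray      # (4, p_z)
    sigma_eps: np.ndarray  # (4,)
    Sigma: np.ndarray      # (4, 4)
    theta: np.ndarray      # (n, 4)

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.sigma_eps = np.asarray(self.sigma_eps, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))


def log_prior(
    hp: HierParams,
    beta_sd: float = BETA_PRIOR_SD,
    sigma_upper: float = SIGMA_EPS_UPPER,
    wishart_df: int = WISHART_DF,
) -> float:
    """Log prior density of the hyperparameters; -inf outside support."""
    lp = float(
        stats.norm.logpdf(hp.beta, scale=beta_sd).sum()
        + stats.norm.logpdf(hp.gamma, scale=beta_sd).sum()
    )
    if np.any(hp.sigma_eps <= 0) or np.any(hp.sigma_eps >= sigma_upper):
        return -np.inf
    lp += -4.0 * np.log(sigma_upper)
    try:
        prec = np.linalg.inv(hp.Sigma)
        # Wishart(I_4, df) prior on the precision matrix.
        lp += float(stats.wishart.logpdf(prec, df=wishart_df, scale=np.eye(4)))
    except np.linalg.LinAlgError:
        return -np.inf
    if not np.isfinite(lp):
        return -np.inf
    return lp


@dataclass
class DesignMatrices:
    """Participant-level (x) and session-level (z) covariate matrices.

    ``x`` rows are indexed by participant (intercept, centred age, sex);
    ``z`` rows are indexed by session record (strong-role indicator,
    session-1 indicator).  ``participant_index[s]`` maps session record s
    to its participant's row in ``x``.
    """

    x: np.ndarray
    z: np.ndarray
    participants: list[str]
    participant_index: np.ndarray
    x_names: tuple[str, ...] = ("intercept", "age_c", "male")
    z_names: tuple[str, ...] = ("strong_role", "session1")

    @property
    def p_x(self) -> int:
        return self.x.shape[1]

    @property
    def p_z(self) -> int:
        return self.z.shape[1]


def build_design(records: pd.DataFrame) -> DesignMatrices:
    """Build design matrices from one row per participant-session.

    ``records`` needs columns participant, session, role, age, sex; the
    returned x matrix is per participant (age mean-centred across
    participants), z per session record.
    """
    required = {"participant", "session", "role", "age", "sex"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing covariate columns: {sorted(missing)}")
    if not np.isfinite(records[["age", "sex", "role"]].to_numpy(dtype=float)).all():
        raise ValueError("covariate columns must be finite")
    per_part = (
        records[["participant", "age", "sex"]]
        .drop_duplicates("participant")
        .reset_index(drop=True)
    )
    participants = per_part["participant"].tolist()
    age_c = per_part["age"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    x = np.column_stack(
        [np.ones(len(per_part)), age_c, per_part["sex"].to_numpy(dtype=float)]
    )
    lookup = {p: i for i, p in enumerate(participants)}
    pidx = records["participant"].map(lookup).to_numpy(dtype=int)
    z = np.column_stack(
        [
            records["role"].to_numpy(dtype=float),
            (records["session"].to_numpy(dtype=int) == 1).astype(float),
        ]
    )
    return DesignMatrices(x=x, z=z, participants=participants, participant_index=pidx)
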