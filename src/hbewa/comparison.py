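"""Watanabe–Akaike information criterion (WAIC) model comparison.

WAIC scores a fitted Bayesian model from its pointwise posterior
log-likelihoods: the log pointwise predictive density

    lppd = sum_i ln( mean over draws of exp(loglik_i) )

minus a complexity penalty equal to the summed posterior variance of the
pointwise log-likelihood (the variance-based effective number of
parameters, p_waic), reported on the deviance scale

    waic = -2 * (lppd - p_waic).

Smaller WAIC indicates the better fit/complexity balance.  A "point" is
one participant-session-round choice, the grain at which the categorical
likelihood factorises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass(frozen=True)
class WAICResult:
    model: str
    waic: float
    lppd: float
    p_waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.pointwise_lppd)


def waic(loglik: np.ndarray, model: str = "") -> WAICResult:
    """WAIC from a (draws, points) pointwise log-likelihood matrix."""
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError(f"expected a 2-d (draws, points) matrix, got shape {loglik.shape}")
    n_draws, n_points = loglik.shape
    if n_draws < 2:
        raise ValueError("WAIC needs at least 2 posterior draws (variance undefined)")
    if n_points < 1:
        raise ValueError("WAIC needs at least one data point")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("pointwise log-likelihoods must be finite")
    lppd_i = logsumexp(loglik, axis=0) - np.log(n_draws)
    p_i = loglik.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WAICResult(
        model=model,
        waic=-2.0 * (lppd - p_waic),
        lppd=lppd,
        p_waic=p_waic,
        pointwise_lppd=lppd_i,
        pointwise_p=p_i,
    )


def rank_models(results: list[WAICResult]) -> pd.DataFrame:
    """Rank candidate models by ascending WAIC with pairwise differences.

    All models must score the same data points.
    """
    if len(results) < 2:
        raise ValueError("model ranking needs at least two models")
    n_points = {r.n_points for r in results}
    if len(n_points) > 1:
        raise ValueError(f"models score different numbers of points: {sorted(n_points)}")
    order = sorted(results, key=lambda r: r.waic)
    best = order[0].waic
    return pd.DataFrame(
        {
            "model": [r.model for r in order],
            "waic": [r.waic for r in order],
            "p_waic": [r.p_waic for r in order],
            "d_waic": [r.waic - best for r in order],
        }
    )
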