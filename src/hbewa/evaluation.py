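"""Parameter-recovery metrics and posterior summaries.

Recovery of simulated ground truth is measured per parameter family by
the mean absolute error of posterior means (reported x100) and by the
coverage of quantile-based 95% credible intervals, averaged over
participant-sessions.  Session effects (within-participant differences
between the two sessions) are scored by the coefficient of determination
about the identity line.  Regression coefficients are summarised on the
odds-ratio scale (logit-linked families) or relative-risk scale (lam),
and random-effect covariances are converted to correlations.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .comparison import WAICResult
from .ewa import FAMILIES
from .inference import PosteriorSamples


def _check_keys(estimates: Mapping, truth: Mapping) -> None:
    missing = sorted(set(truth) - set(estimates))
    extra = sorted(set(estimates) - set(truth))
    if missing or extra:
        raise KeyError(
            f"estimate/truth key mismatch; missing from estimates: {missing[:5]}, "
            f"missing from truth: {extra[:5]}"
        )


def mae(estimates: Mapping, truth: Mapping) -> float:
    """100 x mean absolute error of posterior means against truth."""
    _check_keys(estimates, truth)
    errs = [abs(estimates[k] - truth[k]) for k in truth]
    return 100.0 * float(np.mean(errs))


def coverage(draws: Mapping, truth: Mapping, level: float = 0.95) -> float:
    """Fraction of quantile-based credible intervals containing the truth."""
    _check_keys(draws, truth)
    a = (1.0 - level) / 2.0
    hits = 0
    for k, x in draws.items():
        x = np.asarray(x)
        if len(x) < 100:
            raise ValueError(f"need >= 100 draws per parameter, got {len(x)} for {k}")
        lo, hi = np.quantile(x, [a, 1.0 - a])
        hits += lo <= truth[k] <= hi
    return hits / len(truth)


def covariance_to_correlation(sigma_draws: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-draw correlations corr_ij = S_ij / sqrt(S_ii S_jj) and summaries.

    Returns the (draws, 4, 4) correlation array and a summary table with
    posterior mean and central 95% interval per off-diagonal entry.
    """
    sig = np.asarray(sigma_draws, dtype=float)
    if sig.ndim != 3 or sig.shape[1:] != (4, 4):
        raise ValueError(f"expected (draws, 4, 4) covariance draws, got {sig.shape}")
    d = np.sqrt(np.einsum("kii->ki", sig))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("covariance draws must have positive diagonals")
    corr = sig / d[:, :, None] / d[:, None, :]
    corr[:, np.arange(4), np.arange(4)] = 1.0
    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            x = corr[:, i, j]
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append(
                {
                    "pair": f"{FAMILIES[i]}-{FAMILIES[j]}",
                    "mean": float(x.mean()),
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                    "excludes_zero": bool(lo > 0 or hi < 0),
                }
            )
    return corr, pd.DataFrame(rows)


def effect_scale_summary(draws: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Summarise link-scale coefficient draws on the OR / RR scale.

    Exponentiates the draws (odds ratio for logit-linked families,
    relative risk for the log-linked sensitivity) and reports mean, SD,
    central quantiles, and whether the 95% interval excludes 1.
    """
    rows = []
    for name, x in draws.items():
        ex = np.exp(np.asarray(x, dtype=float))
        q = np.quantile(ex, [0.025, 0.5, 0.975])
        rows.append(
            {
                "effect": name,
                "mean": float(ex.mean()),
                "sd": float(ex.std(ddof=1)) if len(ex) > 1 else 0.0,
                "q2.5": float(q[0]),
                "median": float(q[1]),
                "q97.5": float(q[2]),
                "excludes_one": bool(q[0] > 1 or q[2] < 1),
            }
        )
    return pd.DataFrame(rows)


def session_effect_recovery(
    estimates: Mapping[tuple[str, int], float],
    truth: Mapping[tuple[str, int], float],
) -> float:
    """R^2 about the identity line for session-1 minus session-2 effects.

    Both mappings are keyed by (participant, session); each participant
    must appear with both sessions.  Estimated per-participant differences
    are compared against true differences with residuals taken against
    y = x, so R^2 can be negative when estimates are worse than predicting
    zero change; such values are reported as is.
    """
    parts = sorted({p for p, _ in truth})
    est_d, true_d = [], []
    for pid in parts:
        for mapping, out in ((estimates, est_d), (truth, true_d)):
            try:
                out.append(mapping[(pid, 1)] - mapping[(pid, 2)])
            except KeyError as exc:
                raise KeyError(f"participant {pid} missing a session: {exc}") from exc
    est_d = np.asarray(est_d)
    true_d = np.asarray(true_d)
    ss_res = float(np.sum((est_d - true_d) ** 2))
    ss_tot = float(np.sum((true_d - true_d.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def truth_mapping(truth: pd.DataFrame, family: str) -> dict[tuple[str, int], float]:
    """Ground-truth table -> {(participant, session): value} for one family."""
    sel = truth[truth["family"] == family]
    return {
        (str(p), int(s)): float(v)
        for p, s, v in zip(sel["participant"], sel["session"], sel["value"])
    }


def recovery_report(
    fits: Mapping[str, PosteriorSamples],
    truth: pd.DataFrame,
    waics: Mapping[str, WAICResult] | None = None,
) -> pd.DataFrame:
    """Recovery table: MAE (x100) and 95% CI coverage per model and family."""
    rows = []
    for model, ps in fits.items():
        for fam in FAMILIES:
            tr = truth_mapping(truth, fam)
            est = ps.session_posterior_mean(fam)
            dr = {
                k: ps.session_draws(fam)[:, i]
                for i, k in enumerate(ps.session_keys)
            }
            row = {
                "model": model,
                "family": fam,
                "mae": mae(est, tr),
                "coverage": coverage(dr, tr),
            }
            if waics is not None and model in waics:
                row["waic"] = waics[model].waic
                row["p_waic"] = waics[model].p_waic
            rows.append(row)
    return pd.DataFrame(rows)
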