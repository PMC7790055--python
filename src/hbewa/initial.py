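"""Initial attractions and experience weight.

The EWA recursions need starting values ``V_k(0)`` and ``N(0)``.  These are
fixed before posterior sampling, exogenously to the hierarchical model:
``N(0) = 1`` (a weak prior belief in the initial attractions), and
``V_k(0)`` estimated by maximum likelihood from the first few rounds of
play pooled over all participants sharing the same role and session —
players of the same role in the same session are assumed to start from the
same attractions.

Because ``lam * V(0)`` is not jointly identifiable, the sensitivity is
fixed at 1 for this step and the attractions are anchored to mean zero.
The multinomial softmax MLE then has the closed form

    V0_k = ln(n_k + c) - mean_k ln(n_k + c)

where ``n_k`` counts pooled choices of strategy ``k`` and ``c = 0.5`` is an
additive smoothing constant that keeps never-chosen strategies finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .ewa import SessionData
from .game import GameSpec


@dataclass
class InitialConditions:
    """Initial attractions per (session, role) group and the shared N(0)."""

    v0: dict[tuple[int, int], np.ndarray]
    n0: float = 1.0

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError(f"N(0) must be positive, got {self.n0}")

    def for_session(self, session: int, role: int) -> np.ndarray:
        key = (session, role)
        if key not in self.v0:
            raise KeyError(f"no initial attractions for session {session}, role {role}")
        return self.v0[key]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"session": s, "role": r, "strategy": k, "v0": float(v)}
            for (s, r), vec in sorted(self.v0.items())
            for k, v in enumerate(vec)
        ]
        return pd.DataFrame(rows)


def estimate_initial_attractions(
    sessions: Iterable[SessionData],
    game: GameSpec,
    n_rounds: int = 5,
    smoothing: float = 0.5,
) -> InitialConditions:
    """Smoothed multinomial MLE of V(0), pooled by (session, role); N(0)=1."""
    if n_rounds < 1:
        raise ValueError(f"n_rounds must be >= 1, got {n_rounds}")
    counts: dict[tuple[int, int], np.ndarray] = {}
    for sd in sessions:
        key = (sd.session, sd.role)
        if key not in counts:
            counts[key] = np.zeros(game.n_actions(sd.role))
        first = sd.choices[: min(n_rounds, sd.n_rounds)]
        np.add.at(counts[key], first, 1.0)
    if not counts:
        raise ValueError("no sessions provided for initial-attraction estimation")
    v0 = {}
    for key, n_k in counts.items():
        if n_k.sum() == 0:
            raise ValueError(f"empty first-round group for (session, role) = {key}")
        logn = np.log(n_k + smoothing)
        v0[key] = logn - logn.mean()
    return InitialConditions(v0=v0, n0=1.0)
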