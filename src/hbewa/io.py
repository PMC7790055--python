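"""Long-format data table reading, validation and writing.

The canonical on-disk format is a headed CSV with one row per
participant-session-round:

    participant, session, round, role, choice, opponent_choice, age, sex

(participant, session, round) must be unique, rounds contiguous from 1
within each session, and choices valid for the row's role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewa import SessionData
from .game import PATENT_RACE, GameSpec
from .hierarchy import DesignMatrices, build_design

log = logging.getLogger("hbewa")

REQUIRED_COLUMNS = [
    "participant", "session", "round", "role",
    "choice", "opponent_choice", "age", "sex",
]


@dataclass
class GameData:
    """Validated dataset: raw table, per-session sequences and designs."""

    frame: pd.DataFrame
    sessions: list[SessionData]
    design: DesignMatrices
    game: GameSpec

    @property
    def n_participants(self) -> int:
        return len(self.design.participants)

    @property
    def session_keys(self) -> list[tuple[str, int]]:
        return [(sd.participant, sd.session) for sd in self.sessions]


def from_frame(
    df: pd.DataFrame,
    game: GameSpec = PATENT_RACE,
    start: int = 6,
) -> GameData:
    """Validate a long-format table and split it into sessions."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.reset_index(drop=True)

    dup = df.duplicated(subset=["participant", "session", "round"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValueError(f"duplicated (participant, session, round) keys at rows {rows}")

    for role in sorted(df["role"].unique()):
        if role not in (0, 1):
            raise ValueError(f"role must be 0 or 1, found {role}")
        sel = df["role"] == role
        bad = sel & ~df["choice"].between(0, game.endowment(int(role)))
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise ValueError(
                f"choice outside action space 0..{game.endowment(int(role))} "
                f"for role {role} at rows {rows}"
            )
        opp_max = game.endowment(game.opposing(int(role)))
        bad = sel & ~df["opponent_choice"].between(0, opp_max)
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise ValueError(
                f"opponent choice outside action space 0..{opp_max} at rows {rows}"
            )

    sessions: list[SessionData] = []
    records = []
    for (pid, sess), grp in df.groupby(["participant", "session"], sort=True):
        grp = grp.sort_values("round")
        rounds = grp["round"].to_numpy()
        if not np.array_equal(rounds, np.arange(1, len(rounds) + 1)):
            raise ValueError(
                f"rounds not contiguous from 1 for participant {pid} session {sess} "
                f"(rows {grp.index.tolist()[:10]})"
            )
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"role changes mid-session for participant {pid} session {sess}")
        sessions.append(
            SessionData(
                participant=str(pid),
                session=int(sess),
                role=int(roles[0]),
                choices=grp["choice"].to_numpy(),
                opponent_choices=grp["opponent_choice"].to_numpy(),
                start=start,
            )
        )
        records.append(
            {
                "participant": str(pid),
                "session": int(sess),
                "role": int(roles[0]),
                "age": float(grp["age"].iloc[0]),
                "sex": float(grp["sex"].iloc[0]),
            }
        )

    design = build_design(pd.DataFrame(records))
    log.info(
        "loaded %d participants, %d sessions, %d rounds/session",
        design.x.shape[0], len(sessions), sessions[0].n_rounds if sessions else 0,
    )
    return GameData(frame=df, sessions=sessions, design=design, game=game)


def read_data(path, game: GameSpec = PATENT_RACE, start: int = 6) -> GameData:
    """Read and validate a long-format CSV."""
    df = pd.read_csv(path)
    return from_frame(df, game=game, start=start)


def write_data(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
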