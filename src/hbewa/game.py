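"""Two-player normal-form investment games.

The canonical instance is the Patent Race: in every round two players
simultaneously sink part of an integer endowment into R&D.  The strictly
higher investment wins a prize worth ``prize`` units; ties lose the prize
for both; invested units are forfeit regardless of outcome, and the
uninvested remainder of the endowment is kept.  Roles are asymmetric —
the weak player (role 0) is endowed with 4 units and the strong player
(role 1) with 5 — so the weak role chooses among 5 investment levels and
the strong role among 6.

Strategy ``k`` is identified with investing ``k`` units, so action spaces
are the contiguous integers ``0..endowment``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

#: Role codes used throughout the package.
WEAK, STRONG = 0, 1

_ROLES = (WEAK, STRONG)


def _check_role(role: int) -> int:
    if role not in _ROLES:
        raise ValueError(f"unknown role {role!r}; expected 0 (weak) or 1 (strong)")
    return int(role)


@dataclass(frozen=True)
class GameSpec:
    """Payoff structure of a two-role normal-form investment game.

    Parameters
    ----------
    prize
        Award amount ``q`` won by the strictly higher investor.
    endowments
        Integer endowments indexed by role, ``(weak, strong)``.
    """

    prize: int = 10
    endowments: tuple[int, int] = (4, 5)

    def __post_init__(self) -> None:
        if self.prize <= 0:
            raise ValueError(f"prize must be positive, got {self.prize}")
        if len(self.endowments) != 2 or any(e < 1 for e in self.endowments):
            raise ValueError(f"endowments must be two integers >= 1, got {self.endowments}")

    # -- structure ---------------------------------------------------------

    def endowment(self, role: int) -> int:
        return self.endowments[_check_role(role)]

    def opposing(self, role: int) -> int:
        return 1 - _check_role(role)

    def action_space(self, role: int) -> np.ndarray:
        """Ordered admissible investments for ``role``: ``0..endowment``."""
        return np.arange(self.endowment(role) + 1)

    def n_actions(self, role: int) -> int:
        return self.endowment(role) + 1

    # -- payoffs -----------------------------------------------------------

    def payoff(self, role: int, own: int, opponent: int) -> float:
        """Payoff of investing ``own`` against an opponent investing ``opponent``.

        Kept endowment plus the prize iff the own investment strictly
        exceeds the opponent's; ties lose the prize.
        """
        endow = self.endowment(role)
        if not 0 <= own <= endow:
            raise ValueError(
                f"investment {own} outside action space 0..{endow} for role {role}"
            )
        if opponent < 0:
            raise ValueError(f"opponent investment must be >= 0, got {opponent}")
        return float(endow + self.prize * (own > opponent) - own)

    def payoff_matrix(self, role: int) -> np.ndarray:
        """Payoffs ``pi[k, y]`` for each own investment ``k`` and opponent
        investment ``y`` of the opposing role."""
        own = self.action_space(role)[:, None]
        opp = self.action_space(self.opposing(role))[None, :]
        return (self.endowment(role) + self.prize * (own > opp) - own).astype(float)

    # -- configuration -----------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "GameSpec":
        endow = cfg.get("endowments", {"weak": 4, "strong": 5})
        if isinstance(endow, dict):
            endow = (endow["weak"], endow["strong"])
        return cls(prize=int(cfg.get("prize", 10)), endowments=tuple(int(e) for e in endow))

    @classmethod
    def from_yaml(cls, path) -> "GameSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "prize": self.prize,
            "endowments": {"weak": self.endowments[0], "strong": self.endowments[1]},
        }


#: Packaged default: the Patent Race with a 10-unit prize and 4/5 endowments.
PATENT_RACE = GameSpec()
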