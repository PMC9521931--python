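"""2x2 symmetric stage games: validation, presets, and classification.

The framework couples a Prisoner's Dilemma (PD) to a second symmetric 2x2
game, "game B".  Payoffs are named in the PD convention: ``reward`` for
mutual play of the first strategy, ``punishment`` for mutual play of the
second, ``temptation`` for the second strategy against the first, and
``sucker`` for the first against the second.  For game B the first strategy
is "down" (d) and the second "up" (u), so ``reward`` is R_B (mutual down),
``punishment`` P_B (mutual up), ``temptation`` T_B (up against down) and
``sucker`` S_B (down against up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class GameClass(str, Enum):
    """Strategic class of a symmetric 2x2 game."""

    DOMINANCE = "dominance"
    COORDINATION = "coordination"
    ANTI_COORDINATION = "anti_coordination"
    DEGENERATE = "degenerate"


class InvalidGameError(ValueError):
    """Raised for malformed games or invalid game parameters."""


class RolesUndefinedError(ValueError):
    """Raised when soft/hard roles are requested for a game without them."""


@dataclass(frozen=True)
class SymmetricGame2x2:
    """A two-player, two-strategy symmetric game.

    Parameters
    ----------
    reward, sucker, temptation, punishment
        Row-player payoffs for the profiles (1st,1st), (1st,2nd),
        (2nd,1st) and (2nd,2nd) respectively.
    strategy_labels
        Names of the two strategies, e.g. ``("C", "D")`` for the PD and
        ``("d", "u")`` for game B.
    """

    reward: float
    sucker: float
    temptation: float
    punishment: float
    strategy_labels: tuple[str, str] = ("C", "D")

    def __post_init__(self) -> None:
        for name in ("reward", "sucker", "temptation", "punishment"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidGameError(f"payoff {name!r} must be a finite real number, got {v!r}")
        if len(self.strategy_labels) != 2 or self.strategy_labels[0] == self.strategy_labels[1]:
            raise InvalidGameError(f"strategy labels must be two distinct names, got {self.strategy_labels!r}")

    def payoff(self, mine: int, theirs: int) -> float:
        """Row-player payoff; strategy indices 0 (first) and 1 (second)."""
        return ((self.reward, self.sucker), (self.temptation, self.punishment))[mine][theirs]

    @property
    def payoffs(self) -> tuple[float, float, float, float]:
        return (self.reward, self.sucker, self.temptation, self.punishment)

    def relabelled(self) -> "SymmetricGame2x2":
        """The same game with the two strategies exchanged."""
        return SymmetricGame2x2(
            reward=self.punishment,
            sucker=self.temptation,
            temptation=self.sucker,
            punishment=self.reward,
            strategy_labels=(self.strategy_labels[1], self.strategy_labels[0]),
        )

    def to_dict(self) -> dict:
        return {
            "reward": self.reward,
            "sucker": self.sucker,
            "temptation": self.temptation,
            "punishment": self.punishment,
            "strategy_labels": list(self.strategy_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetricGame2x2":
        labels = tuple(d.get("strategy_labels", ("C", "D")))
        return cls(d["reward"], d["sucker"], d["temptation"], d["punishment"], labels)


@dataclass(frozen=True)
class HelpingGameParams:
    """Benefit/cost parameterisation of the donation (helping) game.

    A cooperator pays a cost ``c`` so the opponent receives a benefit
    ``b``; requires 0 < c < b for a valid Prisoner's Dilemma.
    """

    benefit: float
    cost: float

    def __post_init__(self) -> None:
        if not (0 < self.cost < self.benefit):
            raise InvalidGameError(
                f"helping game requires 0 < cost < benefit, got cost={self.cost}, benefit={self.benefit}"
            )


#: Table of named stage-game presets (payoffs as R, S, T, P quadruples).
PRESETS: dict[str, SymmetricGame2x2] = {
    "prisoners_dilemma": SymmetricGame2x2(3, 0, 5, 1, ("C", "D")),
    "snow_drift": SymmetricGame2x2(3, 1, 5, 0, ("d", "u")),
    "battle_of_sexes": SymmetricGame2x2(0, 3, 5, 0, ("d", "u")),
    "leader": SymmetricGame2x2(2, 3, 5, 1, ("d", "u")),
    "stag_hunt": SymmetricGame2x2(5, 0, 1, 1, ("d", "u")),
}


def preset(name: str) -> SymmetricGame2x2:
    """Return a named base game.

    Valid names: ``prisoners_dilemma``, ``snow_drift``, ``battle_of_sexes``,
    ``leader``, ``stag_hunt``.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidGameError(
            f"unknown preset {name!r}; valid presets are {sorted(PRESETS)}"
        ) from None


def classify_game(g: SymmetricGame2x2) -> GameClass:
    """Classify a symmetric 2x2 game.

    Anti-coordination: each strategy is the unique best reply to the other
    (T > R and S > P).  Coordination: each strategy is the unique best reply
    to itself (R > T and P > S).  Dominance: one strategy weakly dominates
    with at least one strict inequality.  Ties that prevent any of these
    classifications map to ``DEGENERATE``.
    """
    r, s, t, p = g.payoffs
    if t > r and s > p:
        return GameClass.ANTI_COORDINATION
    if r > t and p > s:
        return GameClass.COORDINATION
    # weak dominance by the second strategy (t >= r, p >= s) or the first
    if (t >= r and p >= s and (t > r or p > s)) or (r >= t and s >= p and (r > t or s > p)):
        return GameClass.DOMINANCE
    return GameClass.DEGENERATE


def helping_game(params_or_b: HelpingGameParams | float, c: float | None = None) -> SymmetricGame2x2:
    """Build the helping-game PD with R=b-c, S=-c, T=b, P=0.

    Accepts either a :class:`HelpingGameParams` or ``(b, c)`` directly.
    The result always satisfies S < P < R < T and T + S < 2R.
    """
    if isinstance(params_or_b, HelpingGameParams):
        b, c_ = params_or_b.benefit, params_or_b.cost
    else:
        if c is None:
            raise InvalidGameError("helping_game requires both benefit and cost")
        b, c_ = float(params_or_b), float(c)
        HelpingGameParams(b, c_)  # validation
    return SymmetricGame2x2(reward=b - c_, sucker=-c_, temptation=b, punishment=0.0, strategy_labels=("C", "D"))


def cost_of(g: SymmetricGame2x2) -> float:
    """Cost of cooperation P - S of a Prisoner's Dilemma."""
    return g.punishment - g.sucker


@dataclass(frozen=True)
class SoftHardRoles:
    """Role assignment at the asymmetric equilibrium of an anti-coordination game."""

    soft: str
    hard: str
    soft_index: int
    hard_index: int


def soft_hard_roles(g: SymmetricGame2x2) -> SoftHardRoles:
    """Identify the soft (lower-payoff) and hard strategies of an
    anti-coordination game.

    In the asymmetric pure equilibrium one player earns the higher payoff
    (the hard strategy) and the other the lower (the soft strategy).  With
    first-strategy = down and T > S this makes down the soft strategy.
    """
    if classify_game(g) is not GameClass.ANTI_COORDINATION:
        raise RolesUndefinedError("soft/hard roles are defined only for anti-coordination games")
    if g.temptation == g.sucker:
        raise RolesUndefinedError("equilibrium payoffs tie; soft/hard roles undefined")
    if g.temptation > g.sucker:
        soft_idx, hard_idx = 0, 1
    else:
        soft_idx, hard_idx = 1, 0
    labels = g.strategy_labels
    return SoftHardRoles(soft=labels[soft_idx], hard=labels[hard_idx], soft_index=soft_idx, hard_index=hard_idx)
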