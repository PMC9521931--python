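"""The 8-strategy composite game and its static Nash analysis.

A composite strategy is written *abc*: *a* is the PD action (C or D), *b*
the game-B reply to a perceived cooperator, and *c* the reply to a
perceived defector.  The canonical order is

    Cuu, Cud, Cdu, Cdd, Duu, Dud, Ddu, Ddd   (indices 0..7).

Two payoff-matrix constructions are provided: the direct-interaction model
(both stages against the same, perfectly observed opponent) and the
reputation model, where each party misperceives the opponent's PD action
independently with probability eta; the reputation matrix is the exact
expectation over the four perception outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .games import (
    GameClass,
    InvalidGameError,
    SymmetricGame2x2,
    classify_game,
    soft_hard_roles,
)

#: Canonical strategy names, Table-ordered.
STRATEGY_NAMES: tuple[str, ...] = ("Cuu", "Cud", "Cdu", "Cdd", "Duu", "Dud", "Ddu", "Ddd")
STRATEGY_INDEX: dict[str, int] = {n: i for i, n in enumerate(STRATEGY_NAMES)}

# Action coding: PD 0=C, 1=D; game-B replies 0=u, 1=d.
PD_ACTION = np.array([i // 4 for i in range(8)], dtype=np.int64)
REPLY_TO_C = np.array([(i // 2) % 2 for i in range(8)], dtype=np.int64)
REPLY_TO_D = np.array([i % 2 for i in range(8)], dtype=np.int64)
#: REPLIES[s, a] = reply code of strategy s against perceived PD action a.
REPLIES = np.stack([REPLY_TO_C, REPLY_TO_D], axis=1)

NE_TOL = 1e-9


class GameClassError(ValueError):
    """Raised when an operation is requested for the wrong class of game B."""


@dataclass(frozen=True)
class CompositeStrategy:
    """One of the eight *abc* strategies."""

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 7:
            raise ValueError(f"strategy index must be in 0..7, got {self.index}")

    @property
    def name(self) -> str:
        return STRATEGY_NAMES[self.index]

    @property
    def pd_action(self) -> str:
        return "C" if PD_ACTION[self.index] == 0 else "D"

    @property
    def reply_to_C(self) -> str:
        return "u" if REPLY_TO_C[self.index] == 0 else "d"

    @property
    def reply_to_D(self) -> str:
        return "u" if REPLY_TO_D[self.index] == 0 else "d"

    @classmethod
    def from_name(cls, name: str) -> "CompositeStrategy":
        try:
            return cls(STRATEGY_INDEX[name])
        except KeyError:
            raise ValueError(f"unknown strategy {name!r}; valid names: {STRATEGY_NAMES}") from None


STRATEGIES: tuple[CompositeStrategy, ...] = tuple(CompositeStrategy(i) for i in range(8))


def _b_payoff_table(gb: SymmetricGame2x2) -> np.ndarray:
    """Game-B payoff indexed by reply codes (0=u, 1=d); first strategy of gb is d."""
    tab = np.empty((2, 2))
    for mine in range(2):
        for theirs in range(2):
            tab[mine, theirs] = gb.payoff(1 - mine, 1 - theirs)
    return tab


def _pd_payoff_table(pd: SymmetricGame2x2) -> np.ndarray:
    return np.array([[pd.reward, pd.sucker], [pd.temptation, pd.punishment]])


@dataclass(frozen=True)
class TwoStagePayoffMatrix:
    """8x8 row-player payoff matrix of the composite game.

    ``entries[x, y]`` is the payoff of strategy x against strategy y; by
    symmetry the column player's payoff in cell (x, y) is ``entries[y, x]``.
    """

    entries: np.ndarray
    pd: SymmetricGame2x2
    game_b: SymmetricGame2x2
    eta: float = 0.0

    def row(self, name: str) -> np.ndarray:
        return self.entries[STRATEGY_INDEX[name]]

    def cell(self, row: str, col: str) -> float:
        return float(self.entries[STRATEGY_INDEX[row], STRATEGY_INDEX[col]])

    def pd_entries(self) -> np.ndarray:
        """The PD component of every cell."""
        return _pd_payoff_table(self.pd)[np.ix_(PD_ACTION, PD_ACTION)].astype(float)

    def b_entries(self) -> np.ndarray:
        """The game-B component of every cell (expectation over perception noise)."""
        return self.entries - self.pd_entries()


def build_direct_matrix(pd: SymmetricGame2x2, gb: SymmetricGame2x2) -> TwoStagePayoffMatrix:
    """Composite payoff matrix of the direct-interaction model.

    ``entries[x, y] = PD(a_x, a_y) + B(reply_x(a_y), reply_y(a_x))``.
    """
    pdt, bt = _pd_payoff_table(pd), _b_payoff_table(gb)
    entries = np.empty((8, 8))
    for x in range(8):
        for y in range(8):
            ax, ay = PD_ACTION[x], PD_ACTION[y]
            entries[x, y] = pdt[ax, ay] + bt[REPLIES[x, ay], REPLIES[y, ax]]
    return TwoStagePayoffMatrix(entries=entries, pd=pd, game_b=gb, eta=0.0)


def build_reputation_matrix(pd: SymmetricGame2x2, gb: SymmetricGame2x2, eta: float) -> TwoStagePayoffMatrix:
    """Composite matrix with recognition noise eta.

    Each party independently misperceives the opponent's PD action with
    probability eta; the game-B component is the exact expectation over the
    four perception outcomes (no sampling).
    """
    if not 0.0 <= eta <= 1.0:
        raise InvalidGameError(f"eta must lie in [0, 1], got {eta}")
    pdt, bt = _pd_payoff_table(pd), _b_payoff_table(gb)
    w = (1.0 - eta, eta)
    entries = np.empty((8, 8))
    for x in range(8):
        for y in range(8):
            ax, ay = PD_ACTION[x], PD_ACTION[y]
            bexp = 0.0
            for fx in range(2):  # x misperceives y's action?
                for fy in range(2):
                    bexp += w[fx] * w[fy] * bt[REPLIES[x, ay ^ fx], REPLIES[y, ax ^ fy]]
            entries[x, y] = pdt[ax, ay] + bexp
    return TwoStagePayoffMatrix(entries=entries, pd=pd, game_b=gb, eta=eta)


def build_matrix(pd: SymmetricGame2x2, gb: SymmetricGame2x2, eta: float = 0.0) -> TwoStagePayoffMatrix:
    """Direct matrix for eta = 0, reputation matrix otherwise."""
    if eta == 0.0:
        return build_direct_matrix(pd, gb)
    return build_reputation_matrix(pd, gb, eta)


def swap_replies_index() -> np.ndarray:
    """Permutation exchanging every strategy's reply_to_C and reply_to_D."""
    perm = np.empty(8, dtype=np.int64)
    for i in range(8):
        perm[i] = (i // 4) * 4 + (i % 2) * 2 + (i // 2) % 2
    return perm


def enumerate_pure_nash(m: TwoStagePayoffMatrix, tol: float = NE_TOL) -> list[tuple[int, int]]:
    """All ordered pure Nash profiles (row, column), weak equilibria included.

    A cell (i, j) is an equilibrium iff i is a best reply to j and j a best
    reply to i; all 64 cells are checked.
    """
    a = m.entries
    col_max = a.max(axis=0)
    best = a >= col_max[np.newaxis, :] - tol
    return [(i, j) for i in range(8) for j in range(8) if best[i, j] and best[j, i]]


def classify_profile(profile: tuple[int, int]) -> str:
    """'defective' iff both PD actions are D, else 'cooperative'."""
    i, j = profile
    return "defective" if PD_ACTION[i] == 1 and PD_ACTION[j] == 1 else "cooperative"


@dataclass(frozen=True)
class CoopNECondition:
    exists: bool
    cost: float
    threshold: float
    game_class: GameClass


def cooperative_ne_condition(pd: SymmetricGame2x2, gb: SymmetricGame2x2) -> CoopNECondition:
    """Existence rule for a cooperative pure Nash profile.

    The cost of cooperation P − S must be smaller than the coordination
    asymmetry |T_B − S_B| when game B is an anti-coordination game, and
    smaller than the superior-minus-inferior gap |R_B − P_B| when game B is
    a coordination game.  For a dominance-class game B no cooperative
    equilibrium is possible and a :class:`GameClassError` is raised.

    For anti-coordination game B the rule is exact (equivalent to pure-NE
    enumeration finding a cooperative profile).  For coordination game B it
    governs the heterogeneous cooperator–defector equilibria; the
    mutual-cooperation profile (Cdu, Cdu) instead requires T − R below the
    same gap, so the rule is exact whenever P − S = T − R (in particular
    for the helping game, where both equal the cost of cooperation, and
    for the base presets).
    """
    cls = classify_game(gb)
    cost = pd.punishment - pd.sucker
    if cls is GameClass.ANTI_COORDINATION:
        threshold = abs(gb.temptation - gb.sucker)
    elif cls is GameClass.COORDINATION:
        threshold = abs(gb.reward - gb.punishment)
    else:
        raise GameClassError(
            f"no cooperative equilibrium is possible when game B is {cls.value}"
        )
    return CoopNECondition(exists=cost < threshold, cost=cost, threshold=threshold, game_class=cls)


@dataclass(frozen=True)
class MixedProfile:
    """A symmetric mixed-strategy Nash candidate on the composite game."""

    support: tuple[int, ...]
    probabilities: np.ndarray
    verified: bool
    residual: float
    payoff: float | None = None
    note: str = ""

    def prob(self, name: str) -> float:
        return float(self.probabilities[STRATEGY_INDEX[name]])

    def as_dict(self) -> dict[str, float]:
        return {STRATEGY_NAMES[i]: float(self.probabilities[i]) for i in range(8)}


def verify_mixed(m: TwoStagePayoffMatrix, probs: np.ndarray, support: tuple[int, ...], tol: float = NE_TOL) -> MixedProfile | None:
    """Check indifference on the support and absence of profitable deviations."""
    payoffs = m.entries @ probs
    v = float(payoffs[list(support)].mean())
    residual = float(np.abs(payoffs[list(support)] - v).max())
    outside = [i for i in range(8) if i not in support]
    ok = residual <= 1e-8 and (not outside or payoffs[outside].max() <= v + tol)
    if not ok:
        return None
    return MixedProfile(support=tuple(support), probabilities=probs, verified=True, residual=residual, payoff=v)


def solve_mixed_on_support(
    m: TwoStagePayoffMatrix, support, tol: float = NE_TOL
) -> MixedProfile | None:
    """Solve the indifference system on a support and verify the result.

    Returns a verified :class:`MixedProfile` iff the linear system has a
    nonnegative solution against which no outside strategy earns strictly
    more; ``None`` otherwise (including singular, degenerate systems).
    """
    sup = tuple(sorted(STRATEGY_INDEX[s] if isinstance(s, str) else int(s) for s in support))
    if len(sup) == 0 or len(set(sup)) != len(sup):
        raise ValueError("support must be a nonempty set of distinct strategies")
    k = len(sup)
    a = m.entries
    sys = np.zeros((k + 1, k + 1))
    sys[:k, :k] = a[np.ix_(sup, sup)]
    sys[:k, k] = -1.0
    sys[k, :k] = 1.0
    rhs = np.zeros(k + 1)
    rhs[k] = 1.0
    if np.linalg.matrix_rank(sys) < k + 1:
        return None  # degenerate indifference system
    sol = np.linalg.solve(sys, rhs)
    x = sol[:k]
    if (x < -tol).any():
        return None
    probs = np.zeros(8)
    probs[list(sup)] = np.clip(x, 0.0, None)
    probs /= probs.sum()
    return verify_mixed(m, probs, sup, tol=tol)


# ---------------------------------------------------------------------------
# Closed-form equilibria (printed formulas, returned as unverified candidates)
# ---------------------------------------------------------------------------


def _probs_from(pairs: dict[str, float]) -> np.ndarray:
    p = np.zeros(8)
    for name, val in pairs.items():
        p[STRATEGY_INDEX[name]] = val
    return p


@dataclass(frozen=True)
class FullyCooperativeFamily:
    """The one-parameter family of fully cooperative mixed equilibria.

    The indifference constraints fix the two sums
    ``x_Cuu + x_Cud`` and ``x_Cdu + x_Cdd``; the remaining freedom is
    bounded by a no-deviation inequality.  ``printed_bound`` carries the
    literature's closed-form bound for the base Snow Drift payoffs,
    ``x_Cud + x_Cdu < 1/3 - c/2`` (reported verbatim; the matrix-derived
    check used for verification constrains ``x_Cud + x_Cdd`` instead —
    see :func:`fully_cooperative_family_member`).
    """

    x_cuu_plus_x_cud: float
    x_cdu_plus_x_cdd: float
    cost: float
    printed_bound: float | None
    exists: bool


def closed_form_equilibrium(
    pd: SymmetricGame2x2, gb: SymmetricGame2x2, which: str
):
    """Direct substitution of the printed closed-form equilibria.

    ``which`` is one of ``SH1``/``SH2`` (coordination game B: the
    Cdd–Ddu and Cud–Ddu two-strategy equilibria) or ``AC4``/``FC``
    (anti-coordination game B: the four-strategy cooperative equilibrium
    and the fully cooperative family).  Profiles are returned *unverified*:
    they are literal substitutions and may be passed to
    :func:`solve_mixed_on_support`-style verification.  ``FC`` returns a
    :class:`FullyCooperativeFamily` instead of a single profile.
    """
    cls = classify_game(gb)
    R, S, T, P = pd.payoffs
    RB, SB, TB, PB = gb.payoffs
    if which in ("SH1", "SH2"):
        if cls is not GameClass.COORDINATION:
            raise GameClassError(f"{which} requires a coordination-class game B, got {cls.value}")
        if which == "SH1":
            den = P + R - RB - S + SB - T
            pairs = {"Cdd": (P - RB - S + SB) / den, "Ddu": (R - T) / den}
        else:
            den = P + 2 * PB + R - 2 * RB - S - T
            pairs = {"Cud": (P + PB - RB - S) / den, "Ddu": (PB + R - RB - T) / den}
        probs = _probs_from(pairs)
        return MixedProfile(
            support=tuple(np.flatnonzero(probs)),
            probabilities=probs,
            verified=False,
            residual=float("nan"),
            note=f"closed-form substitution ({which})",
        )
    if which == "AC4":
        if cls is not GameClass.ANTI_COORDINATION:
            raise GameClassError(f"AC4 requires an anti-coordination game B, got {cls.value}")
        c = P - S
        den = (PB + RB - SB - TB) * (SB**2 + PB * (2 * RB - SB - TB) + TB**2 - RB * (SB + TB))
        top1 = c * PB + c * RB + PB * RB - c * SB - (c + PB + RB) * TB + TB**2
        top2 = (PB - SB) * (-RB + SB) + c * (PB + RB - SB - TB)
        pairs = {
            "Cuu": (RB - TB) * top1 / den,
            "Cdu": (PB - SB) * top1 / den,
            "Ddu": (TB - RB) * top2 / den,
            "Ddd": (SB - PB) * top2 / den,
        }
        probs = _probs_from(pairs)
        return MixedProfile(
            support=tuple(np.flatnonzero(probs)),
            probabilities=probs,
            verified=False,
            residual=float("nan"),
            note="closed-form substitution (AC4)",
        )
    if which == "FC":
        if cls is not GameClass.ANTI_COORDINATION:
            raise GameClassError(f"FC requires an anti-coordination game B, got {cls.value}")
        den = PB + RB - SB - TB
        p_uc = (RB - TB) / den
        p_dc = (PB - SB) / den
        c = P - S
        # Printed bound is specific to the base Snow Drift payoffs.
        printed = 1.0 / 3.0 - c / 2.0 if gb.payoffs == (3, 1, 5, 0) else None
        exists = fully_cooperative_family_member(gb, c, 0.0, 0.0, pd=pd) is not None
        return FullyCooperativeFamily(
            x_cuu_plus_x_cud=p_uc, x_cdu_plus_x_cdd=p_dc, cost=c, printed_bound=printed, exists=exists
        )
    raise ValueError(f"unknown closed form {which!r}; expected SH1, SH2, AC4 or FC")


def fully_cooperative_family_member(
    gb: SymmetricGame2x2,
    c: float,
    x_cud: float,
    x_cdd: float,
    pd: SymmetricGame2x2 | None = None,
    tol: float = NE_TOL,
) -> MixedProfile | None:
    """Complete and verify one member of the fully cooperative family.

    The free weights are x_Cud and x_Cdd; x_Cuu and x_Cdu follow from the
    indifference constraints.  The profile is returned iff all four weights
    are nonnegative and no defective strategy earns more against it, with
    the no-deviation check computed directly on the composite payoff
    matrix.  Any Prisoner's Dilemma with cost of cooperation ``c`` gives
    the same verdict; a helping game with that cost is used when ``pd`` is
    not supplied.
    """
    if classify_game(gb) is not GameClass.ANTI_COORDINATION:
        raise GameClassError("the fully cooperative family requires an anti-coordination game B")
    if not (0.0 <= x_cud <= 1.0 and 0.0 <= x_cdd <= 1.0):
        raise ValueError("free weights must lie in [0, 1]")
    if pd is None:
        from .games import helping_game

        if c <= 0:
            return None
        pd = helping_game(c + 1.0, c)
    RB, SB, TB, PB = gb.payoffs
    den = PB + RB - SB - TB
    x_cuu = (RB - TB) / den - x_cud
    x_cdu = (PB - SB) / den - x_cdd
    probs = _probs_from({"Cuu": x_cuu, "Cud": x_cud, "Cdu": x_cdu, "Cdd": x_cdd})
    if (probs < -tol).any():
        return None
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        return None
    probs /= total
    m = build_direct_matrix(pd, gb)
    support = tuple(i for i in range(4) if probs[i] > tol) or (0,)
    payoffs = m.entries @ probs
    v = float(payoffs[:4][probs[:4] > tol].mean()) if (probs[:4] > tol).any() else float(payoffs[0])
    if payoffs[4:].max() > v + tol:
        return None
    residual = float(np.abs(payoffs[:4][probs[:4] > tol] - v).max())
    return MixedProfile(support=support, probabilities=probs, verified=True, residual=residual, payoff=v)


def fully_cooperative_cost_threshold(
    gb: SymmetricGame2x2, lo: float = 1e-6, hi: float = 4.0, tol: float = 1e-8
) -> float:
    """Largest cost of cooperation admitting a fully cooperative equilibrium.

    Located by bisection on the feasibility of the family's least-binding
    member (both free weights zero); 2/3 for the base Snow Drift payoffs.
    """
    if fully_cooperative_family_member(gb, lo, 0.0, 0.0) is None:
        return float("nan")
    while fully_cooperative_family_member(gb, hi, 0.0, 0.0) is not None:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fully_cooperative_family_member(gb, mid, 0.0, 0.0) is None:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def matrix_to_dataframe(m: TwoStagePayoffMatrix):
    """The 8x8 row-player matrix as a labelled pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(m.entries, index=STRATEGY_NAMES, columns=STRATEGY_NAMES)


def nash_report(m: TwoStagePayoffMatrix) -> dict:
    """Pure-equilibrium census of a composite matrix, JSON-serialisable."""
    profiles = enumerate_pure_nash(m)
    return {
        "eta": m.eta,
        "profiles": [
            {
                "row": STRATEGY_NAMES[i],
                "column": STRATEGY_NAMES[j],
                "classification": classify_profile((i, j)),
                "row_payoff": float(m.entries[i, j]),
                "column_payoff": float(m.entries[j, i]),
            }
            for i, j in profiles
        ],
        "n_cooperative": sum(1 for p in profiles if classify_profile(p) == "cooperative"),
        "n_defective": sum(1 for p in profiles if classify_profile(p) == "defective"),
    }
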