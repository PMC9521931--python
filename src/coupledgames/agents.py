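"""Stochastic finite-population simulation in a well-mixed population.

Generations are synchronous (Wright–Fisher-like): every generation the
population is randomly matched, payoffs are collected from one PD partner
and one game-B partner per individual (the same partner in the direct
model, independent matchings in the reputation model), and the next
generation of N offspring is sampled with replacement with probability
proportional to payoff, each offspring mutating with probability nu to one
of the other seven strategies uniformly.  Sampling noise is retained
throughout; expected payoffs are never substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .games import SymmetricGame2x2
from .twostage import PD_ACTION, REPLIES, STRATEGY_NAMES, _b_payoff_table, _pd_payoff_table
from .observables import soft_reply_code


class PayoffSignError(ValueError):
    """Raised when payoffs cannot be used as reproduction weights."""


@dataclass
class AbmParams:
    """Simulation parameters for the well-mixed agent-based model."""

    pd: SymmetricGame2x2
    game_b: SymmetricGame2x2
    model: str = "direct"  # or "reputation"
    nu: float = 0.005
    eta: float = 0.0
    pi0: float = 0.0
    n: int = 10_000
    generations: int = 20_000
    cadence: int = 10

    def __post_init__(self) -> None:
        if self.model not in ("direct", "reputation"):
            raise ValueError("model must be 'direct' or 'reputation'")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must lie in [0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.n % 2 != 0 or self.n < 2:
            raise ValueError("population size N must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class Population:
    """Strategy assignment of N individuals (composite-strategy ids 0..7)."""

    strategies: np.ndarray

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=np.int8)
        if self.strategies.ndim != 1 or self.strategies.size % 2 != 0:
            raise ValueError("population must be a flat array of even size")

    @property
    def n(self) -> int:
        return self.strategies.size

    def counts(self) -> np.ndarray:
        return np.bincount(self.strategies.astype(np.int64), minlength=8)


def _stage_tables(params: AbmParams):
    """Lookup tables: PD payoffs (8x8) and game-B payoffs with perception
    flips, ``b4[x, y, fx, fy]`` where fx flips x's perception of y."""
    cached = params.__dict__.get("_tables")
    if cached is not None:
        return cached
    pdt = _pd_payoff_table(params.pd)
    bt = _b_payoff_table(params.game_b)
    pd8 = pdt[np.ix_(PD_ACTION, PD_ACTION)].astype(float)
    b4 = np.empty((8, 8, 2, 2))
    for x in range(8):
        for y in range(8):
            for fx in range(2):
                for fy in range(2):
                    b4[x, y, fx, fy] = bt[
                        REPLIES[x, PD_ACTION[y] ^ fx], REPLIES[y, PD_ACTION[x] ^ fy]
                    ]
    params.__dict__["_tables"] = (pd8, b4)
    return pd8, b4


def play_generation(pop: Population, params: AbmParams, rng: np.random.Generator):
    """One round of matched play; returns per-individual payoffs and a
    record of realized game-B actions/payoffs used by the observables.

    Direct model: one uniform random perfect matching; replies condition on
    the partner's actual PD action.  Reputation model: independent
    matchings for the PD and game B; each party's perception of its game-B
    partner's PD action flips independently with probability eta.
    """
    pd8, b4 = _stage_tables(params)
    strat = pop.strategies.astype(np.int64)
    n = strat.size
    payoffs = np.empty(n)
    b_payoff = np.empty(n)
    b_action = np.empty(n, dtype=np.int64)  # realized reply code, 1 = d
    if params.model == "direct":
        perm = rng.permutation(n)
        a, b = strat[perm[0::2]], strat[perm[1::2]]
        pa = pd8[a, b] + b4[a, b, 0, 0]
        pb = pd8[b, a] + b4[b, a, 0, 0]
        payoffs[perm[0::2]], payoffs[perm[1::2]] = pa, pb
        b_payoff[perm[0::2]], b_payoff[perm[1::2]] = b4[a, b, 0, 0], b4[b, a, 0, 0]
        b_action[perm[0::2]] = REPLIES[a, PD_ACTION[b]]
        b_action[perm[1::2]] = REPLIES[b, PD_ACTION[a]]
    else:
        perm = rng.permutation(n)
        a, b = strat[perm[0::2]], strat[perm[1::2]]
        payoffs[perm[0::2]], payoffs[perm[1::2]] = pd8[a, b], pd8[b, a]
        perm2 = rng.permutation(n)
        a2, b2 = strat[perm2[0::2]], strat[perm2[1::2]]
        fa = (rng.random(n // 2) < params.eta).astype(np.int64)
        fb = (rng.random(n // 2) < params.eta).astype(np.int64)
        bpa, bpb = b4[a2, b2, fa, fb], b4[b2, a2, fb, fa]
        payoffs[perm2[0::2]] += bpa
        payoffs[perm2[1::2]] += bpb
        b_payoff[perm2[0::2]], b_payoff[perm2[1::2]] = bpa, bpb
        b_action[perm2[0::2]] = REPLIES[a2, PD_ACTION[b2] ^ fa]
        b_action[perm2[1::2]] = REPLIES[b2, PD_ACTION[a2] ^ fb]
    payoffs += params.pi0
    record = {
        "pd_action": PD_ACTION[strat],  # 0 = C
        "b_action": b_action,
        "b_payoff": b_payoff,
    }
    return payoffs, record


def reproduce(pop: Population, payoffs: np.ndarray, nu: float, rng: np.random.Generator) -> Population:
    """Wright–Fisher resampling proportional to payoff, with mutation."""
    if (payoffs < 0).any() or payoffs.sum() <= 0:
        raise PayoffSignError(
            "payoffs must be nonnegative with positive total to act as "
            "reproduction weights; increase the base payoff pi0"
        )
    n = pop.n
    parents = rng.choice(n, size=n, p=payoffs / payoffs.sum())
    child = pop.strategies[parents].copy()
    mutate = rng.random(n) < nu
    k = int(mutate.sum())
    if k:
        child[mutate] = (child[mutate] + rng.integers(1, 8, size=k)) % 8
    return Population(child)


@dataclass
class AbmResult:
    trajectory: pd.DataFrame
    final_population: Population
    tail_freqs: np.ndarray
    label: str
    seed: int

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": self.seed,
            "tail_frequencies": {STRATEGY_NAMES[i]: float(self.tail_freqs[i]) for i in range(8)},
        }


def _realized_observables(record, params: AbmParams):
    s_a = np.where(record["pd_action"] == 0, 1.0, -1.0)
    soft = soft_reply_code(params.game_b)
    s_b = np.where(record["b_action"] == soft, 1.0, -1.0)
    corr = float((s_a * s_b).mean() - s_a.mean() * s_b.mean())
    coop = record["pd_action"] == 0
    pi_c = float(record["b_payoff"][coop].mean()) if coop.any() else float("nan")
    pi_d = float(record["b_payoff"][~coop].mean()) if (~coop).any() else float("nan")
    den = pi_c + pi_d
    dpi = (pi_c - pi_d) / den if den and not np.isnan(den) else float("nan")
    return float((s_b > 0).mean()), dpi, corr


def run_abm(
    params: AbmParams,
    seed: int,
    init: Population | np.ndarray | None = None,
    tail_window: int | None = None,
    classify_floor: float | None = None,
) -> AbmResult:
    """Run the agent-based model and label its tail state.

    The trajectory records strategy frequencies, the cooperator density,
    the realized soft-play density, the game-B payoff asymmetry and the
    PD/game-B correlation every ``cadence`` generations.  The label is
    computed on the tail-window average with the same floor rule as the
    mean-field dynamics (10 nu by default).  Fully seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    if init is None:
        pop = Population(rng.integers(0, 8, size=params.n))
    elif isinstance(init, Population):
        pop = Population(init.strategies.copy())
    else:
        pop = Population(np.asarray(init))
    if pop.n != params.n:
        raise ValueError(f"initial population size {pop.n} != params.n {params.n}")
    tail_window = tail_window or max(1, params.generations // 20)
    rows = []
    tail_accum = np.zeros(8)
    tail_count = 0
    for t in range(params.generations):
        payoffs, record = play_generation(pop, params, rng)
        if t % params.cadence == 0 or t == params.generations - 1:
            f = pop.counts() / pop.n
            rho_soft, dpi, corr = _realized_observables(record, params)
            rows.append(
                {
                    "t": t,
                    **{f"freq_{STRATEGY_NAMES[i]}": f[i] for i in range(8)},
                    "rho_C": float(f[:4].sum()),
                    "rho_d": rho_soft,
                    "delta_pi": dpi,
                    "corr": corr,
                }
            )
        if t >= params.generations - tail_window:
            tail_accum += pop.counts() / pop.n
            tail_count += 1
        pop = reproduce(pop, payoffs, params.nu, rng)
    tail = tail_accum / tail_count
    floor = 10.0 * params.nu if classify_floor is None else classify_floor
    rho_c = tail[:4].sum()
    if rho_c <= floor:
        label = "defective"
    elif 1.0 - rho_c <= floor:
        label = "fully_cooperative"
    else:
        label = "cooperative"
    traj = pd.DataFrame(rows)
    traj.insert(0, "seed", seed)
    traj.insert(1, "N", params.n)
    return AbmResult(trajectory=traj, final_population=pop, tail_freqs=tail, label=label, seed=seed)
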