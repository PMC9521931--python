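"""Structured-population dynamics on a periodic square lattice.

Individuals occupy an L x L torus with von Neumann (4-neighbour)
connectivity.  Each time step every site plays both stages with all four
neighbours, collecting ``pi0`` plus the summed stage payoffs, and then all
sites synchronously imitate a model drawn from their extended
neighbourhood (self + 4 neighbours) with probability proportional to
payoff, finally mutating with probability nu to a uniformly random other
strategy.  In the reputation model each directed perception on an edge
flips independently with probability eta and is resampled every step; the
two perception draws of one encounter are shared by both parties' payoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .games import SymmetricGame2x2
from .twostage import PD_ACTION, REPLIES, STRATEGY_NAMES, _b_payoff_table, _pd_payoff_table
from .observables import soft_reply_code


@dataclass
class LatticeParams:
    pd: SymmetricGame2x2
    game_b: SymmetricGame2x2
    model: str = "direct"
    nu: float = 0.005
    eta: float = 0.0
    pi0: float = 0.0
    steps: int = 6000
    cadence: int = 10
    snapshot_cadence: int | None = None
    synchronous: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("direct", "reputation"):
            raise ValueError("model must be 'direct' or 'reputation'")
        if not 0.0 <= self.nu <= 1.0 or not 0.0 <= self.eta <= 1.0:
            raise ValueError("nu and eta must lie in [0, 1]")


@dataclass
class LatticeState:
    """Strategy ids (0..7) on an L x L periodic grid."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")
        if ((self.grid < 0) | (self.grid > 7)).any():
            raise ValueError("grid entries must be strategy ids 0..7")

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.grid.ravel().astype(np.int64), minlength=8)


def _tables(params: LatticeParams):
    cached = params.__dict__.get("_tables")
    if cached is not None:
        return cached
    pdt = _pd_payoff_table(params.pd)
    bt = _b_payoff_table(params.game_b)
    pd8 = pdt[np.ix_(PD_ACTION, PD_ACTION)].astype(float)
    b4 = np.empty((8, 8, 2, 2))
    act = np.empty((8, 8, 2), dtype=np.int64)  # realized reply of x vs y given x's flip
    for x in range(8):
        for y in range(8):
            for fx in range(2):
                act[x, y, fx] = REPLIES[x, PD_ACTION[y] ^ fx]
                for fy in range(2):
                    b4[x, y, fx, fy] = bt[REPLIES[x, PD_ACTION[y] ^ fx], REPLIES[y, PD_ACTION[x] ^ fy]]
    params.__dict__["_tables"] = (pd8, b4, act)
    return pd8, b4, act


def lattice_payoffs(state: LatticeState, params: LatticeParams, rng: np.random.Generator):
    """Per-site payoff grid, plus realized game-B action and payoff sums.

    Returns ``(payoffs, b_payoff_sum, soft_play_count)`` where the latter
    two hold each site's total game-B payoff and its number of soft plays
    over the four encounters of this step.
    """
    pd8, b4, act = _tables(params)
    g = state.grid.astype(np.int64)
    pay = np.full(g.shape, float(params.pi0))
    b_sum = np.zeros(g.shape)
    d_plays = np.zeros(g.shape)
    noisy = params.model == "reputation" and params.eta > 0.0
    for axis in (0, 1):
        nb = np.roll(g, -1, axis=axis)
        if noisy:
            f_self = (rng.random(g.shape) < params.eta).astype(np.int64)
            f_nb = (rng.random(g.shape) < params.eta).astype(np.int64)
        else:
            f_self = f_nb = np.zeros(g.shape, dtype=np.int64)
        p_self = pd8[g, nb] + b4[g, nb, f_self, f_nb]
        p_nb = pd8[nb, g] + b4[nb, g, f_nb, f_self]
        pay += p_self
        pay += np.roll(p_nb, 1, axis=axis)
        b_sum += b4[g, nb, f_self, f_nb]
        b_sum += np.roll(b4[nb, g, f_nb, f_self], 1, axis=axis)
        d_plays += act[g, nb, f_self]
        d_plays += np.roll(act[nb, g, f_nb], 1, axis=axis)
    return pay, b_sum, d_plays


def imitation_step(
    state: LatticeState,
    payoffs: np.ndarray,
    nu: float,
    rng: np.random.Generator,
    draws: dict | None = None,
) -> LatticeState:
    """Synchronous payoff-proportional imitation in the extended
    neighbourhood, followed by mutation.

    ``draws`` may pre-supply the grid-shaped random fields (keys
    ``choice``, ``mut_mask``, ``mut_shift``), which makes the update a
    deterministic function of state, payoffs and draws — used e.g. to test
    translation invariance.
    """
    g = state.grid
    stack_s = np.stack([g, np.roll(g, -1, 0), np.roll(g, 1, 0), np.roll(g, -1, 1), np.roll(g, 1, 1)])
    stack_p = np.stack(
        [payoffs, np.roll(payoffs, -1, 0), np.roll(payoffs, 1, 0), np.roll(payoffs, -1, 1), np.roll(payoffs, 1, 1)]
    ).astype(float)
    if (stack_p < 0).any():
        raise ValueError("negative payoffs cannot be imitation weights; increase pi0")
    total = stack_p.sum(axis=0)
    dead = total <= 0.0
    if dead.any():
        warnings.warn("all-zero extended neighbourhood; imitating uniformly there", stacklevel=2)
        stack_p[:, dead] = 1.0
        total = stack_p.sum(axis=0)
    if draws is None:
        u_choice = rng.random(g.shape)
        mut_mask = rng.random(g.shape) < nu
        mut_shift = rng.integers(1, 8, size=g.shape)
    else:
        u_choice = draws["choice"]
        mut_mask = draws["mut_mask"]
        mut_shift = draws["mut_shift"]
    cum = np.cumsum(stack_p, axis=0)
    r = u_choice * total
    pick = (r[np.newaxis, :, :] >= cum).sum(axis=0)
    ii, jj = np.indices(g.shape)
    new = stack_s[pick, ii, jj]
    new = np.where(mut_mask, (new + mut_shift) % 8, new)
    return LatticeState(new.astype(np.int8))


@dataclass
class LatticeResult:
    trajectory: pd.DataFrame
    snapshots: list
    final_state: LatticeState
    label: str
    seed: int


def run_lattice(
    params: LatticeParams,
    init: LatticeState | np.ndarray,
    seed: int,
    tail_window: int | None = None,
    classify_floor: float | None = None,
) -> LatticeResult:
    """Run the lattice dynamics, recording densities and observables.

    The trajectory records the eight strategy densities, the cooperator
    density, the realized soft-play density, the game-B payoff asymmetry
    between cooperators and defectors, the PD/game-B correlation and the
    four response densities every ``cadence`` steps; full grids are kept at
    ``snapshot_cadence``.
    """
    rng = np.random.default_rng(seed)
    state = init if isinstance(init, LatticeState) else LatticeState(np.asarray(init))
    soft = soft_reply_code(params.game_b)
    rows, snaps = [], []
    tail_window = tail_window or max(1, params.steps // 20)
    tail_accum, tail_count = np.zeros(8), 0
    for t in range(params.steps):
        pay, b_sum, d_plays = lattice_payoffs(state, params, rng)
        if t % params.cadence == 0 or t == params.steps - 1:
            rows.append(_observe(state, params, b_sum, d_plays, soft, t, seed))
        if params.snapshot_cadence and t % params.snapshot_cadence == 0:
            snaps.append((t, state.grid.copy()))
        if t >= params.steps - tail_window:
            tail_accum += state.counts() / state.grid.size
            tail_count += 1
        state = imitation_step(state, pay, params.nu, rng)
    tail = tail_accum / tail_count
    floor = 10.0 * params.nu if classify_floor is None else classify_floor
    rho_c = tail[:4].sum()
    label = "defective" if rho_c <= floor else ("fully_cooperative" if 1 - rho_c <= floor else "cooperative")
    return LatticeResult(
        trajectory=pd.DataFrame(rows), snapshots=snaps, final_state=state, label=label, seed=seed
    )


def _observe(state, params, b_sum, d_plays, soft, t, seed):
    g = state.grid
    n = g.size
    f = state.counts() / n
    coop = PD_ACTION[g.astype(np.int64)] == 0
    soft_frac = d_plays / 4.0 if soft == 1 else 1.0 - d_plays / 4.0
    s_a = np.where(coop, 1.0, -1.0)
    s_b = 2.0 * soft_frac - 1.0
    corr = float((s_a * s_b).mean() - s_a.mean() * s_b.mean())
    pi_c = float(b_sum[coop].mean()) / 4.0 if coop.any() else float("nan")
    pi_d = float(b_sum[~coop].mean()) / 4.0 if (~coop).any() else float("nan")
    den = pi_c + pi_d
    dpi = (pi_c - pi_d) / den if den and not np.isnan(den) else float("nan")
    d_c = float(f[REPLIES[:, 0] == 1].sum())
    d_d = float(f[REPLIES[:, 1] == 1].sum())
    return {
        "seed": seed,
        "t": t,
        **{f"freq_{STRATEGY_NAMES[i]}": f[i] for i in range(8)},
        "rho_C": float(coop.mean()),
        "rho_d": float(soft_frac.mean()),
        "delta_pi": dpi,
        "corr": corr,
        "u(C)": 1 - d_c,
        "d(C)": d_c,
        "u(D)": 1 - d_d,
        "d(D)": d_d,
    }
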