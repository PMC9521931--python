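"""Summary statistics of a population state, and the S_B–T_B phase scan.

Observables are defined over *realized (or expected) actions*, not over
strategy labels: a conditional strategy has no unconditional game-B action,
so the density of soft play, the payoff asymmetry and the PD/game-B
correlation are computed as exact expectations for mean-field states and
from the last recorded interactions for finite populations.

The ±1 coding assigns +1 to cooperation and to the soft strategy, −1 to
defection and the hard strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .games import GameClass, SymmetricGame2x2, classify_game, preset, soft_hard_roles
from .twostage import PD_ACTION, REPLIES, STRATEGY_NAMES, TwoStagePayoffMatrix, build_matrix


def freqs_from(source) -> np.ndarray:
    """Strategy frequencies of a distribution, population, or lattice."""
    if hasattr(source, "strategies"):
        ids = np.asarray(source.strategies)
    elif hasattr(source, "grid"):
        ids = np.asarray(source.grid)
    else:
        arr = np.asarray(source)
        if arr.shape == (8,) and np.issubdtype(arr.dtype, np.floating):
            return arr / arr.sum()
        ids = arr
    return np.bincount(ids.ravel().astype(np.int64), minlength=8).astype(float) / ids.size


def rho_C(source) -> float:
    """Density of PD cooperators."""
    return float(freqs_from(source)[:4].sum())


def response_densities(source) -> dict[str, float]:
    """Population fractions of the four game-B response rules:
    u(C), d(C), u(D), d(D).  The pairs u(.)+d(.) each sum to one."""
    f = freqs_from(source)
    d_c = float(f[REPLIES[:, 0] == 1].sum())
    d_d = float(f[REPLIES[:, 1] == 1].sum())
    return {"u(C)": 1.0 - d_c, "d(C)": d_c, "u(D)": 1.0 - d_d, "d(D)": d_d}


def soft_reply_code(gb: SymmetricGame2x2 | None) -> int:
    """Reply code (0=u, 1=d) of the soft strategy; d when roles are undefined
    (coordination-class and scan contexts take 'down' literally)."""
    if gb is not None and classify_game(gb) is GameClass.ANTI_COORDINATION and gb.temptation != gb.sucker:
        return 1 if soft_hard_roles(gb).soft == gb.strategy_labels[0] else 0
    return 1


def _play_d_probability(f: np.ndarray, eta: float) -> float:
    """Expected probability that a random focal's realized game-B action is
    d against a random opponent, with recognition noise eta."""
    rho_c = f[:4].sum()
    # P(focal perceives a cooperator) for a random opponent
    p_see_c = rho_c * (1 - eta) + (1 - rho_c) * eta
    d_if_c = f[REPLIES[:, 0] == 1].sum()  # mass replying d to perceived C
    d_if_d = f[REPLIES[:, 1] == 1].sum()
    # Perception is independent of the focal's own rule.
    return float(p_see_c * d_if_c + (1 - p_see_c) * d_if_d)


def rho_d(source, gb: SymmetricGame2x2 | None = None, eta: float = 0.0) -> float:
    """Expected density of soft play in game B under the current composition.

    For an anti-coordination game B the soft action comes from the role
    assignment; otherwise d is taken literally.
    """
    f = freqs_from(source)
    p_d = _play_d_probability(f, eta)
    return p_d if soft_reply_code(gb) == 1 else 1.0 - p_d


def delta_pi(pi_c_b: float, pi_d_b: float) -> float:
    """Normalized game-B payoff difference (pi_C^B - pi_D^B)/(pi_C^B + pi_D^B).

    Positive iff cooperators earn more from game B.  Returns NaN when the
    denominator vanishes (undefined).
    """
    den = pi_c_b + pi_d_b
    if den == 0.0:
        return float("nan")
    return (pi_c_b - pi_d_b) / den


def game_b_payoffs_by_type(freqs, m: TwoStagePayoffMatrix) -> tuple[float, float]:
    """Mean expected game-B payoff of cooperators and of defectors."""
    f = freqs_from(freqs)
    pi_b = m.b_entries() @ f
    rho_c = f[:4].sum()
    rho_dfct = f[4:].sum()
    pi_c = float((f[:4] @ pi_b[:4]) / rho_c) if rho_c > 0 else float("nan")
    pi_d = float((f[4:] @ pi_b[4:]) / rho_dfct) if rho_dfct > 0 else float("nan")
    return pi_c, pi_d


def delta_pi_meanfield(freqs, m: TwoStagePayoffMatrix) -> float:
    pi_c, pi_d = game_b_payoffs_by_type(freqs, m)
    return delta_pi(pi_c, pi_d)


def connected_correlation(s_a: np.ndarray, s_b: np.ndarray) -> float:
    """Connected correlation <s_A s_B> - <s_A><s_B> of realized ±1-coded
    PD actions and game-B actions across the population."""
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if s_a.size == 0:
        raise ValueError("at least one interaction must be recorded")
    return float((s_a * s_b).mean() - s_a.mean() * s_b.mean())


def connected_correlation_meanfield(
    freqs, gb: SymmetricGame2x2, eta: float = 0.0
) -> float:
    """Exact-expectation connected correlation for a mean-field state.

    The focal's PD action is coded +1 for C; its expected game-B action
    against a random opponent is coded +1 for the soft action.
    """
    f = freqs_from(freqs)
    soft = soft_reply_code(gb)
    rho_c = f[:4].sum()
    p_see_c = rho_c * (1 - eta) + (1 - rho_c) * eta
    # per-strategy probability of playing d
    p_d = p_see_c * (REPLIES[:, 0] == 1) + (1 - p_see_c) * (REPLIES[:, 1] == 1)
    p_soft = p_d if soft == 1 else 1.0 - p_d
    s_b = 2.0 * p_soft - 1.0  # expected coded game-B action per strategy
    s_a = np.where(PD_ACTION == 0, 1.0, -1.0)
    return float((f * s_a * s_b).sum() - (f @ s_a) * (f @ s_b))


@dataclass(frozen=True)
class ObservableSet:
    rho_C: float
    rho_d: float
    delta_pi: float
    corr: float
    response: dict

    def as_dict(self) -> dict:
        return {
            "rho_C": self.rho_C,
            "rho_d": self.rho_d,
            "delta_pi": self.delta_pi,
            "corr": self.corr,
            **self.response,
        }


def meanfield_observables(freqs, m: TwoStagePayoffMatrix) -> ObservableSet:
    """The full observable set for a mean-field state on matrix m."""
    return ObservableSet(
        rho_C=rho_C(freqs),
        rho_d=rho_d(freqs, m.game_b, m.eta),
        delta_pi=delta_pi_meanfield(freqs, m),
        corr=connected_correlation_meanfield(freqs, m.game_b, m.eta),
        response=response_densities(freqs),
    )


# ---------------------------------------------------------------------------
# S_B - T_B phase scan
# ---------------------------------------------------------------------------


def defect_biased_distribution() -> np.ndarray:
    """The scan's defection-favoring initial family: 90% of the mass on
    Dud (defect, play hard with cooperators and soft with defectors — the
    defection-favoring norm) plus a 10% uniform background.

    An even spread over all four defective strategies would not do: it
    loads mass on Ddd/Ddu, which play softly with cooperators, and in the
    anti-coordination regime that composition already lies in the
    cooperative basin."""
    f = np.full(8, 0.1 / 8.0)
    f[STRATEGY_NAMES.index("Dud")] += 0.9
    return f


@dataclass(frozen=True)
class PhaseScanResult:
    table: pd.DataFrame
    boundary: list

    def bistable_grid(self) -> pd.DataFrame:
        sub = self.table[self.table.init == "center"][["S_B", "T_B", "bistable"]]
        return sub.pivot(index="T_B", columns="S_B", values="bistable")


def phase_scan(
    s_b_grid,
    t_b_grid,
    r_b: float = 3.0,
    p_b: float = 1.0,
    pd_game: SymmetricGame2x2 | None = None,
    nu: float = 0.005,
    eta: float = 0.0,
    pi0: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 200_000,
    classify_floor: float | None = None,
) -> PhaseScanResult:
    """Stationary cooperation across the (S_B, T_B) plane.

    Every cell is run from the center initial condition and from the
    defect-biased condition; a cell is bistable iff the two labels differ.
    The bistability boundary is reported at grid-edge resolution as the set
    of edges between adjacent cells whose bistability flags differ, and the
    soft strategy of each anti-coordination cell is recorded.
    """
    from .meanfield import center_distribution, classify_state, DynamicsConfig, evolve_batch

    if pd_game is None:
        pd_game = preset("prisoners_dilemma")
    s_vals = [float(s) for s in s_b_grid]
    t_vals = [float(t) for t in t_b_grid]
    cells = [(sb, tb) for sb in s_vals for tb in t_vals]
    games = [
        SymmetricGame2x2(r_b, sb, tb, p_b, ("d", "u")) for sb, tb in cells
    ]
    mats = np.stack([build_matrix(pd_game, g, eta).entries for g in games])
    lo = mats.min() + pi0
    if lo < -1e-12:
        raise ValueError(f"minimum payoff over the scan is {lo:.3g} < 0; increase pi0")
    floor = 10.0 * nu if classify_floor is None else classify_floor
    inits = {"center": center_distribution(), "defect_biased": defect_biased_distribution()}
    # One reference config only for labelling (floor semantics).
    ref_cfg = DynamicsConfig(pd_game, games[0], nu=nu, eta=eta, pi0=pi0, classify_floor=floor)
    rows = []
    labels_by_init = {}
    for init_name, init in inits.items():
        x0 = np.tile(init, (len(cells), 1))
        x, _, conv, _, _ = evolve_batch(x0, mats, nu, pi0, tol, max_iter)
        labels = [
            classify_state(x[i], ref_cfg) if conv[i] else "unclassified" for i in range(len(cells))
        ]
        labels_by_init[init_name] = labels
        for i, (sb, tb) in enumerate(cells):
            g = games[i]
            soft = None
            if classify_game(g) is GameClass.ANTI_COORDINATION and g.temptation != g.sucker:
                soft = soft_hard_roles(g).soft
            rows.append(
                {
                    "S_B": sb,
                    "T_B": tb,
                    "init": init_name,
                    "label": labels[i],
                    "rho_C": float(x[i, :4].sum()),
                    "soft_strategy": soft,
                }
            )
    coop = {"cooperative", "fully_cooperative"}
    bistable = [
        (labels_by_init["center"][i] in coop) != (labels_by_init["defect_biased"][i] in coop)
        for i in range(len(cells))
    ]
    table = pd.DataFrame(rows)
    table["bistable"] = bistable * 2  # same flag for both init rows
    # Boundary edges between adjacent cells where bistability toggles.
    flag = {cells[i]: bistable[i] for i in range(len(cells))}
    boundary = []
    for i, sb in enumerate(s_vals):
        for j, tb in enumerate(t_vals):
            if i + 1 < len(s_vals) and flag[(sb, tb)] != flag[(s_vals[i + 1], tb)]:
                boundary.append({"axis": "S_B", "between": [[sb, tb], [s_vals[i + 1], tb]]})
            if j + 1 < len(t_vals) and flag[(sb, tb)] != flag[(sb, t_vals[j + 1])]:
                boundary.append({"axis": "T_B", "between": [[sb, tb], [sb, t_vals[j + 1]]]})
    return PhaseScanResult(table=table, boundary=boundary)
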