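"""Discrete-time replicator–mutator dynamics on the 8-simplex.

One generation maps a strategy distribution rho to

    rho_x(t+1) = sum_y  M[x, y] * rho_y * pi_y / pibar,

where ``pi_y = pi0 + (A rho)_y`` is the expected payoff of strategy y on
the composite matrix A, ``pibar`` the mean payoff, and M the uniform
mutation kernel with ``M[x, x] = 1 - nu`` and ``M[x, y] = nu / 7``
off-diagonal.  Payoffs act as reproduction weights, so every expected
payoff must be nonnegative wherever the dynamics runs; the base payoff
``pi0`` shifts all payoffs to guarantee this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .games import SymmetricGame2x2
from .twostage import STRATEGY_NAMES, TwoStagePayoffMatrix, build_matrix

LABELS = ("cooperative", "defective", "fully_cooperative", "unclassified")


class PositivityError(ValueError):
    """Raised when payoffs cannot serve as reproduction weights."""


def center_distribution() -> np.ndarray:
    return np.full(8, 0.125)


def as_distribution(freqs, tol: float = 1e-12) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.shape != (8,):
        raise ValueError(f"a strategy distribution has 8 entries, got shape {f.shape}")
    if (f < -tol).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be nonnegative and sum to 1")
    return np.clip(f, 0.0, None) / f.sum()


@dataclass
class DynamicsConfig:
    """Parameters of the mean-field dynamics.

    ``classify_floor`` defaults to ``10 * nu``: frequencies at or below the
    mutation-pressure scale are treated as absent when labelling states.
    """

    pd: SymmetricGame2x2
    game_b: SymmetricGame2x2
    nu: float = 0.005
    eta: float = 0.0
    pi0: float = 0.0
    tol: float = 1e-12
    max_iter: int = 1_000_000
    classify_floor: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError(f"mutation rate nu must lie in [0, 1], got {self.nu}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"recognition noise eta must lie in [0, 1], got {self.eta}")
        if self.pi0 < 0:
            raise ValueError(f"base payoff pi0 must be nonnegative, got {self.pi0}")
        # The minimum expected payoff over the simplex is attained at a
        # vertex, i.e. at the minimum matrix entry.
        lo = float(self.matrix.entries.min()) + self.pi0
        if lo < -1e-12:
            raise PositivityError(
                f"minimum payoff over the simplex is {lo:.6g} < 0; increase pi0 by at least {-lo:.6g}"
            )

    @cached_property
    def matrix(self) -> TwoStagePayoffMatrix:
        return build_matrix(self.pd, self.game_b, self.eta)

    @cached_property
    def mutation_matrix(self) -> np.ndarray:
        m = np.full((8, 8), self.nu / 7.0)
        np.fill_diagonal(m, 1.0 - self.nu)
        return m

    @property
    def floor(self) -> float:
        return 10.0 * self.nu if self.classify_floor is None else self.classify_floor


@dataclass(frozen=True)
class FixedPointResult:
    distribution: np.ndarray
    converged: bool
    iterations: int
    residual: float
    label: str

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "residual": float(self.residual),
            "frequencies": {STRATEGY_NAMES[i]: float(self.distribution[i]) for i in range(8)},
        }


def expected_payoffs(
    freqs: np.ndarray, m: TwoStagePayoffMatrix, pi0: float = 0.0, check: bool = True
) -> np.ndarray:
    """Expected payoff of each strategy, ``pi = pi0 + A @ rho``.

    Raises :class:`PositivityError` if any payoff is negative, or zero for
    a strategy actually present (a zero payoff for an absent strategy is a
    well-defined zero reproduction weight).
    """
    f = np.asarray(freqs, dtype=float)
    pi = pi0 + m.entries @ f
    if check:
        bad = np.flatnonzero((pi < -1e-12) | ((pi <= 0.0) & (f > 1e-15)))
        if bad.size:
            raise PositivityError(
                f"nonpositive expected payoff for {STRATEGY_NAMES[bad[0]]} (pi={pi[bad[0]]:.6g}); increase pi0"
            )
    return pi


def step(freqs: np.ndarray, cfg: DynamicsConfig) -> np.ndarray:
    """One replicator–mutator generation."""
    f = np.asarray(freqs, dtype=float)
    pi = expected_payoffs(f, cfg.matrix, cfg.pi0)
    pibar = float(f @ pi)
    if pibar <= 0.0:
        raise PositivityError("mean payoff is nonpositive; increase pi0")
    return cfg.mutation_matrix @ (f * pi / pibar)


def classify_state(freqs: np.ndarray, cfg: DynamicsConfig) -> str:
    """Label a state: defective if cooperators are at/below the floor,
    fully_cooperative if defectors are, cooperative otherwise."""
    rho_c = float(np.asarray(freqs)[:4].sum())
    if rho_c <= cfg.floor:
        return "defective"
    if 1.0 - rho_c <= cfg.floor:
        return "fully_cooperative"
    return "cooperative"


def evolve_batch(
    states: np.ndarray,
    matrices: np.ndarray,
    nu: float,
    pi0: float,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    record_every: int | None = None,
):
    """Iterate the dynamics for a batch of states (and per-row matrices).

    ``states`` is (n, 8); ``matrices`` is (8, 8) shared or (n, 8, 8) per
    row.  Returns ``(states, iterations, converged, residuals, history)``;
    ``history`` is a list of (t, states-copy) pairs when ``record_every``
    is set, else None.
    """
    x = np.array(states, dtype=float, copy=True)
    n = x.shape[0]
    shared = matrices.ndim == 2
    mut = np.full((8, 8), nu / 7.0)
    np.fill_diagonal(mut, 1.0 - nu)
    active = np.ones(n, dtype=bool)
    iters = np.zeros(n, dtype=np.int64)
    resid = np.full(n, np.inf)
    history = [] if record_every else None
    if record_every:
        history.append((0, x.copy()))
    for t in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        xa = x[idx]
        if shared:
            pi = pi0 + xa @ matrices.T
        else:
            pi = pi0 + np.einsum("nij,nj->ni", matrices[idx], xa)
        if (pi < -1e-9).any():
            raise PositivityError("negative expected payoff encountered; increase pi0")
        pi = np.clip(pi, 0.0, None)
        pibar = (xa * pi).sum(axis=1, keepdims=True)
        if (pibar <= 0).any():
            raise PositivityError("mean payoff is nonpositive; increase pi0")
        xn = (xa * pi / pibar) @ mut.T
        r = np.abs(xn - xa).sum(axis=1)
        x[idx] = xn
        iters[idx] = t
        resid[idx] = r
        active[idx[r < tol]] = False
        if record_every and t % record_every == 0:
            history.append((t, x.copy()))
    converged = ~active
    return x, iters, converged, resid, history


def run_to_stationarity(
    d0: np.ndarray, cfg: DynamicsConfig, record_every: int | None = None
) -> FixedPointResult | tuple[FixedPointResult, list]:
    """Iterate :func:`step` until the L1 residual drops below tolerance.

    Non-convergence (including cycles) is reported via ``converged=False``
    with the last state; the label is then ``unclassified``.
    """
    x0 = as_distribution(d0)[np.newaxis, :]
    x, iters, conv, resid, history = evolve_batch(
        x0, cfg.matrix.entries, cfg.nu, cfg.pi0, cfg.tol, cfg.max_iter, record_every
    )
    converged = bool(conv[0])
    label = classify_state(x[0], cfg) if converged else "unclassified"
    result = FixedPointResult(
        distribution=x[0], converged=converged, iterations=int(iters[0]), residual=float(resid[0]), label=label
    )
    if record_every:
        return result, [(t, h[0]) for t, h in history]
    return result


def assess_stability(fp: np.ndarray, cfg: DynamicsConfig, eps: float = 1e-7):
    """Linear stability of a fixed point, restricted to the simplex.

    The step map is differentiated numerically along the directions
    ``e_i - fp`` (which stay inside the simplex) and the Jacobian is
    restricted to the sum-zero tangent space.  Stable iff the spectral
    radius is below ``1 - 1e-6``; eigenvalues within ``1e-6`` of the unit
    circle are reported as neutral directions.
    """
    f = as_distribution(fp)
    if np.abs(step(f, cfg) - f).sum() > 1e-8:
        raise ValueError("input is not a fixed point within tolerance")
    # Directional derivatives J v_i for v_i = e_i - fp.
    v = np.eye(8) - f[np.newaxis, :]
    images = np.empty((8, 8))
    for i in range(8):
        images[i] = (step(f + eps * v[i], cfg) - step(f, cfg)) / eps
    # Orthonormal basis of the sum-zero subspace.
    ones = np.ones((8, 1))
    q, _ = np.linalg.qr(np.eye(8) - ones @ ones.T / 8.0)
    b = q[:, :7]
    c = b.T @ v.T  # coordinates of the v_i in the tangent basis, (7, 8)
    jt = (b.T @ images.T) @ np.linalg.pinv(c)
    eig = np.linalg.eigvals(jt)
    radius = float(np.abs(eig).max())
    stable = radius < 1.0 - 1e-6
    neutral = [complex(z) for z in eig if abs(abs(z) - 1.0) <= 1e-6]
    return stable, radius, neutral


def fully_cooperative_sweep(
    gb: SymmetricGame2x2,
    costs,
    nu: float = 1e-3,
    pi0: float = 5.0,
    benefit: float = 2.0,
    tol: float = 1e-12,
    max_iter: int = 200_000,
):
    """Cost sweep locating the fully-cooperative phase of the dynamics.

    For each cost the stationary defector density is measured at ``nu``
    and ``nu/2`` from the center initial condition and extrapolated to the
    zero-mutation limit (Richardson: ``2 rho_D(nu/2) - rho_D(nu)``).  The
    extrapolation is needed because the fully cooperative family is
    neutral at zero mutation, so its mutant load is an order of magnitude
    above the usual ~nu scale and a fixed-floor rule on the raw density
    would misplace the phase boundary.  A cost is labelled
    ``fully_cooperative`` when the extrapolated defector density is at or
    below ``10 nu``.
    """
    from .games import helping_game

    rows = []
    for c in costs:
        b = benefit if benefit > c else c + 1.0
        hg = helping_game(b, c)
        dens = {}
        for mu in (nu, nu / 2.0):
            cfg = DynamicsConfig(hg, gb, nu=mu, pi0=pi0, tol=tol, max_iter=max_iter)
            r = run_to_stationarity(center_distribution(), cfg)
            dens[mu] = float(r.distribution[4:].sum())
        extrapolated = 2.0 * dens[nu / 2.0] - dens[nu]
        rows.append(
            {
                "cost": float(c),
                "rho_D": dens[nu],
                "rho_D_half_nu": dens[nu / 2.0],
                "rho_D_extrapolated": extrapolated,
                "label": "fully_cooperative" if extrapolated <= 10.0 * nu else "cooperative",
            }
        )
    return rows


@dataclass(frozen=True)
class BasinReport:
    n_samples: int
    seed: int
    fractions: dict
    standard_errors: dict
    conditioning: str | None = None
    bins: list | None = None

    def as_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "fractions": self.fractions,
            "standard_errors": self.standard_errors,
        }
        if self.conditioning:
            d["conditioning"] = self.conditioning
            d["bins"] = self.bins
        return d


def sample_simplex(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform (flat Dirichlet) sample of n points on the 8-simplex."""
    return rng.dirichlet(np.ones(8), size=n)


def estimate_basin(
    cfg: DynamicsConfig,
    n_samples: int,
    seed: int,
    conditioning: str | None = None,
    n_bins: int = 10,
    max_iter: int | None = None,
) -> BasinReport:
    """Basin-of-attraction fractions from random initial conditions.

    Initial distributions are sampled uniformly on the simplex, each is run
    to stationarity, and the fraction of runs ending in each label is
    reported with binomial standard errors.  With ``conditioning`` set to
    ``rho_C_init`` or ``rho_d_init``, the probability of the cooperative
    labels is additionally binned by the initial aggregate.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = sample_simplex(n_samples, rng)
    x, _, conv, _, _ = evolve_batch(
        x0.copy(), cfg.matrix.entries, cfg.nu, cfg.pi0, cfg.tol, max_iter or cfg.max_iter
    )
    labels = np.array(
        [classify_state(x[i], cfg) if conv[i] else "unclassified" for i in range(n_samples)]
    )
    fractions = {lab: float((labels == lab).mean()) for lab in LABELS}
    ses = {
        lab: float(np.sqrt(fractions[lab] * (1 - fractions[lab]) / n_samples)) for lab in LABELS
    }
    bins = None
    if conditioning is not None:
        if conditioning == "rho_C_init":
            agg = x0[:, :4].sum(axis=1)
        elif conditioning == "rho_d_init":
            from .observables import rho_d

            agg = np.array([rho_d(x0[i], cfg.game_b, cfg.eta) for i in range(n_samples)])
        else:
            raise ValueError("conditioning must be 'rho_C_init' or 'rho_d_init'")
        coop = np.isin(labels, ("cooperative", "fully_cooperative"))
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        bins = []
        for k in range(n_bins):
            mask = (agg >= edges[k]) & (agg < edges[k + 1] if k < n_bins - 1 else agg <= edges[k + 1])
            cnt = int(mask.sum())
            bins.append(
                {
                    "lo": float(edges[k]),
                    "hi": float(edges[k + 1]),
                    "n": cnt,
                    "p_cooperative": float(coop[mask].mean()) if cnt else float("nan"),
                }
            )
    return BasinReport(
        n_samples=n_samples,
        seed=seed,
        fractions=fractions,
        standard_errors=ses,
        conditioning=conditioning,
        bins=bins,
    )
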