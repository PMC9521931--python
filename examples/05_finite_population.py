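"""Finite-population (Wright-Fisher) simulation versus the mean field.

Runs the direct-interaction model in a population of 10,000 from a
random start and compares the tail-averaged strategy frequencies with
the replicator cooperative fixed point.
"""

import numpy as np

import coupledgames as cg
from coupledgames import agents, meanfield as mf
from coupledgames.agents import AbmParams

pd_game = cg.preset("prisoners_dilemma")
sd = cg.preset("snow_drift")

params = AbmParams(pd_game, sd, n=10_000, nu=0.005, generations=2000, cadence=100)
res = agents.run_abm(params, seed=1, tail_window=300)
cfg = mf.DynamicsConfig(pd_game, sd, nu=0.005)
fp = mf.run_to_stationarity(mf.center_distribution(), cfg).distribution

print(f"tail label: {res.label}")
print("tail freqs:", np.round(res.tail_freqs, 4))
print("mean field:", np.round(fp, 4))
print(f"L-infinity distance: {np.abs(res.tail_freqs - fp).max():.4f}")
print(res.trajectory[["t", "rho_C", "rho_d", "delta_pi", "corr"]].iloc[[0, 2, 5, 10, -1]].to_string(index=False))
print(
    "\nThe rapid rise of rho_C after an initial dip reproduces the two-phase\n"
    "dynamics: soft-with-cooperators norms accumulate first, cooperation follows."
)
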