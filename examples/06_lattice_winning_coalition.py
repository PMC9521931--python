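"""Structured population: a cooperative coalition invades a hostile norm.

Starts a 100x100 periodic lattice entirely from Dud (defect; play hard
with cooperators, soft with defectors - a defection-favoring norm) with
rare mutations.  Cuu and Ddu form a winning coalition - Cuu feeds Ddu in
the PD, Ddu defers to Cuu in game B - and cooperation rises anyway.
"""

import coupledgames as cg
from coupledgames import lattice as lat
from coupledgames.interface import make_fixture
from coupledgames.lattice import LatticeParams

pd_game = cg.preset("prisoners_dilemma")
sd = cg.preset("snow_drift")
params = LatticeParams(pd_game, sd, nu=1e-4, steps=2000, cadence=250)
g0 = make_fixture("monomorphic:Dud", "grid", side=100, seed=5)
res = lat.run_lattice(params, g0, seed=5)

cols = ["t", "rho_C", "freq_Cuu", "freq_Cdu", "freq_Ddu", "freq_Dud"]
print(res.trajectory[cols].to_string(index=False))
print(
    f"\nFinal cooperator density {res.trajectory.rho_C.iloc[-1]:.3f}: population\n"
    "structure removes bistability - cooperation emerges even from an all-Dud start."
)
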