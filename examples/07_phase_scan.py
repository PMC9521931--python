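"""Phase scan over the structure of game B.

Fixes R_B = 3, P_B = 1 and scans (S_B, T_B).  Where game B is itself a
PD (S_B < 1, T_B > 3) cooperation never evolves; in the anti-coordination
region a cooperative fixed point appears and the dynamics becomes
bistable.  The bistability boundary is reported at grid resolution.
"""

import numpy as np

import coupledgames as cg
from coupledgames import observables as ob

scan = ob.phase_scan(
    s_b_grid=np.linspace(0.0, 4.0, 5),
    t_b_grid=np.linspace(2.0, 6.0, 5),
    pd_game=cg.preset("prisoners_dilemma"),
    nu=0.005,
    max_iter=150_000,
)
center = scan.table[scan.table.init == "center"]
print("stationary rho_C from the center initial condition:")
print(center.pivot(index="T_B", columns="S_B", values="rho_C").round(3).to_string())
print("\nbistable cells (center vs defection-favoring init disagree):")
print(scan.bistable_grid().to_string())
print(f"\n{len(scan.boundary)} bistability-boundary edges at grid resolution")
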