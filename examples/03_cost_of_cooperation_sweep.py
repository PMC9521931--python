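"""Everything depends on the cost of cooperation, not its benefit.

Uses the helping-game Prisoner's Dilemma (R=b-c, T=b, P=0, S=-c) coupled
to the base Snow Drift game.  The fully cooperative equilibrium family
exists up to cost 2/3 (located exactly by bisection), and the replicator
dynamics leaves the fully cooperative phase near that cost.
"""

import coupledgames as cg
from coupledgames import meanfield as mf
from coupledgames.twostage import fully_cooperative_cost_threshold

sd = cg.preset("snow_drift")
thr = fully_cooperative_cost_threshold(sd)
print(f"Fully cooperative equilibria exist for cost c < {thr:.6f} (= 2/3)")

rows = mf.fully_cooperative_sweep(sd, costs=[0.2, 0.4, 0.55, 0.75, 0.9], nu=1e-3, pi0=5.0)
print("\ncost   rho_D(nu)  rho_D(nu/2)  extrapolated  label")
for r in rows:
    print(
        f"{r['cost']:.2f}   {r['rho_D']:.4f}     {r['rho_D_half_nu']:.4f}       "
        f"{r['rho_D_extrapolated']:+.4f}      {r['label']}"
    )
print(
    "\nThe extrapolated defector density vanishes below the threshold: only\n"
    "mutation sustains defectors there, while above it they coexist stably."
)
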