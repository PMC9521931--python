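"""Static Nash analysis of the composite (two-stage) game.

Builds the 8x8 payoff matrix of a Prisoner's Dilemma coupled to a Snow
Drift game, enumerates its pure equilibria, and evaluates the simple
existence rule: a cooperative equilibrium exists iff the cost of
cooperation P - S is smaller than the coordination asymmetry T_B - S_B.
"""

import coupledgames as cg
from coupledgames.twostage import STRATEGY_NAMES, matrix_to_dataframe

pd_game = cg.preset("prisoners_dilemma")
snow_drift = cg.preset("snow_drift")
m = cg.build_direct_matrix(pd_game, snow_drift)

print("Row-player payoffs of the composite game (PD + Snow Drift):")
print(matrix_to_dataframe(m).to_string())

print("\nPure Nash profiles (row, column) and their class:")
for i, j in cg.enumerate_pure_nash(m):
    kind = cg.classify_profile((i, j))
    print(f"  ({STRATEGY_NAMES[i]}, {STRATEGY_NAMES[j]})  {kind}")

cond = cg.cooperative_ne_condition(pd_game, snow_drift)
print(
    f"\nCost of cooperation P-S = {cond.cost}, coordination asymmetry "
    f"T_B-S_B = {cond.threshold}: cooperative equilibrium exists = {cond.exists}"
)
print(
    "The profile (Cuu, Ddu) couples the games: the defector plays softly\n"
    "with the cooperator, whose game-B gain offsets the cost of cooperating."
)
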