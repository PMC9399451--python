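"""Stepwise model selection, on a worked example and on simulated data.

Part 1 applies the three-step selection (omission rate, AUC difference,
AICc) to a published table of four screened candidate models from a
salamander habitat-suitability study. Part 2 evaluates a small grid on
simulated data end to end.
"""

import pandas as pd

from maxhab import environment, evaluate, simulate
from maxhab.datasets import published_survivor_table
from maxhab.simulate import LandscapeParams

# --- Part 1: published worked example ---------------------------------
grid = published_survivor_table()
print(grid.to_frame().to_string(index=False))
chosen, audit = evaluate.stepwise_select(grid)
print(f"\nchosen: feature class {chosen.config.feature_class}, "
      f"multiplier {chosen.config.regularization_multiplier:g}, "
      f"AICc {chosen.aicc}, {chosen.n_params} parameters")
# The linear+quadratic model at multiplier 2 wins the final minimum-AICc
# step; note its ΔAICc of 32.17 is relative to the full 16-model grid.

# --- Part 2: a small grid on simulated data ----------------------------
stack, truth = simulate.generate_landscape(
    LandscapeParams(grid_width=120, grid_height=120, seed=7)
)
occ = simulate.sample_presences(truth, stack, n=80, seed=8)
bg = environment.sample_background(stack, n=2000, seed=9)
pres_t = environment.extract(stack, occ.records[["x", "y"]], role="presence")
bg_t = environment.extract(stack, bg, role="background")
table = pd.concat([pres_t, bg_t], ignore_index=True)
kinds = {n: stack.kinds[n] for n in stack.names}

result, models = evaluate.run_grid(
    table, kinds, feature_classes=("L", "LQ"), multipliers=(1.0, 2.0),
    seed=10, max_folds=10,
)
print("\nsimulated grid:")
print(result.to_frame().round(3).to_string(index=False))
chosen2, audit2 = evaluate.stepwise_select(result)
print("selection audit:", audit2["step1_kept"], "->", audit2["chosen"])
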