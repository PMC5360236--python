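"""Evolving reaction norms: networks generalize the equity rule.

Runs a shortened continuum-of-productivities experiment in which each
individual's reward and MAR are produced by evolvable 2-5-1 logistic
networks, then prints the population-mean MAR surface over productivity
pairs never seen verbatim during evolution. Takes ~2 minutes; the longer
desk-scale recipe (equisim.recipes) sharpens the surface toward
MAR(own, other) = own / (own + other).
"""

import numpy as np

from equisim import Params, gain_rate_table, mean_policy_surface, \
    run_experiment

params = Params(mode="continuum", n=150, L=100.0, beta=1.0, tau=0.01,
                m=0.01, weight_mut_sd=0.5, generations=800, seed=3)
result = run_experiment(params, record_every=100)
state = result.final_state

surf = mean_policy_surface(state, params, which="mar", grid_size=5)
axis = np.unique(surf.own)
print("population-mean MAR(own, other):")
print("own\\other " + "  ".join(f"{x:5.2f}" for x in axis))
for own in axis:
    row = surf[surf.own == own].sort_values("other").mean_output
    print(f"{own:8.2f}  " + "  ".join(f"{v:5.3f}" for v in row))
print("\n(analytic target: own/(own+other); demanding more when you")
print("produce more, less when the partner produces more)")

tbl = gain_rate_table(state, params)
slope = np.polyfit(tbl.productivity, tbl.gain_rate, 1)[0]
print(f"\nregression of lifetime gain rate on productivity: "
      f"slope {slope:.2f} (equity predicts 1: you are paid what you"
      " contribute)")
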