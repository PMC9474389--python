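"""Simulate birth-death trees and measure their shape.

Trees are grown forward in time: every lineage draws a speciation
waiting time (and optionally an extinction time) from a chosen
distribution, and the simulation stops once the target number of extant
tips is reached.  Two summary statistics describe the result:

* beta (Aldous' beta-splitting parameter): topology balance; 0 under a
  pure-birth (Yule) process, negative for imbalanced trees.
* gamma (Pybus-Harvey): distribution of node times; standard normal
  with mean 0 under pure birth, negative when splits crowd near the root.
"""

import numpy as np

import phasetree as pt

rng = np.random.default_rng(7)

yule = pt.WaitingTimeModel(speciation=("exponential", {"rate": 1.0}))
heavy = pt.WaitingTimeModel(speciation=("ph_dec", dict(x=0.1, y=0.93, z=10.0)))

for name, model in [("exponential (Yule)", yule), ("ph_dec heavy-tail", heavy)]:
    trees = pt.simulate_trees(model, 60, 100, rng)
    splits = pt.extract_splits(trees)
    est = pt.beta_ci(splits, pt.beta_mle(splits))
    gammas = np.array([pt.gamma_statistic(t) for t in trees])
    print(f"{name}: 100 trees of 60 tips")
    print(
        f"  treeset beta = {est.beta_hat:6.3f} "
        f"[{est.ci_lower:.3f}, {est.ci_upper:.3f}]"
    )
    print(f"  mean gamma   = {gammas.mean():6.3f} (sd {gammas.std(ddof=1):.3f})")

print(
    "\n-> the Yule beta CI covers 0 and mean gamma is near 0; the\n"
    "   heavy-tailed speciation clock pushes beta negative (imbalance),\n"
    "   the direction empirical phylogenies show."
)

tree = pt.simulate_trees(yule, 8, 1, rng)[0]
print("\nOne 8-tip Yule tree in Newick form:")
print(" ", pt.write_newick(tree))
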