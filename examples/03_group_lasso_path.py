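"""Trace the logistic group-Lasso regularization path on simulated data.

The path starts at lambda_max (all 11 property groups excluded) and
relaxes the grouped penalty; groups entering earlier (at larger lambda)
carry stronger association with the outcome.  The four causal properties
of the simulation should enter first.
"""

import numpy as np

from tcrnp import FitConfig, fit_path, make_scenario

ds = make_scenario("n300_p70_baln_lin", rng=1)
path = fit_path(ds.X.values, ds.y, ds.spec,
                config=FitConfig(grid_length=40, grid_ratio=0.01))

support = path.group_support()
print(f"lambda grid: {path.lambdas[0]:.2f} down to {path.lambdas[-1]:.4f} "
      f"({len(path.lambdas)} points)\n")
print("entry order (first grid lambda at which each property enters):")
entries = []
for g, name in enumerate(ds.spec.names):
    hit = np.flatnonzero(support[:, g])
    lam = path.lambdas[hit[0]] if hit.size else None
    entries.append((lam if lam is not None else -1, name, g))
for lam, name, g in sorted(entries, reverse=True):
    tag = " (causal)" if g in ds.truth_groups else ""
    print(f"  {name:<26s} {'never' if lam < 0 else f'{lam:8.3f}'}{tag}")
print("\nGroups entering at larger lambda are more strongly associated with "
      "the simulated outcome; the causal properties should lead.")
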