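"""Miniature selection-performance benchmark.

Repeats simulate -> select -> score over a few replicates of one
scenario and reports mean sensitivity, FDR, F1 and the pairwise-Jaccard
stability of the selected-group lists.  (The full study uses N=100
replicates over 12 scenarios; this is a fast illustration.)
"""

import logging

from tcrnp import FitConfig, run_benchmark

logging.getLogger("tcrnp").setLevel(logging.ERROR)  # constant-column notices

report = run_benchmark(
    scenarios=["n200_p70_baln_lin"],
    methods=["p-group-lasso", "cv-group-lasso"],
    N=4, K=10, tau=0.5, seed=2,
    config=FitConfig(grid_length=40, grid_ratio=0.01),
    level="group",
)

print(report.aggregate.pivot_table(index="method", columns="metric",
                                   values="value").round(3).to_string())
print("\nsensitivity: fraction of the 4 causal properties recovered; "
      "FDR: fraction of selected groups that are noise;\n"
      "stability: mean Jaccard overlap of selections across replicates. "
      "Permutation tuning trades a little sensitivity for far fewer "
      "false positives.")
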