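"""Build a clonotype similarity network and inspect per-cluster properties.

Generates a toy repertoire, connects CDR3 sequences at Levenshtein
distance <= 1, and prints the property table for the retained clusters
(>= 2 nodes).  NA entries mark properties undefined for a cluster shape:
on a 2-node cluster assortativity, transitivity, closeness
centralization and central eigenvector have no definition.
"""

from tcrnp import repertoire_properties, simulate_toy_repertoire

rep = simulate_toy_repertoire(n_clones=60, mutation_rate=0.6, rng=7, patient_id="demo")
table = repertoire_properties(rep, max_dist=1, min_size=2)

print(f"repertoire: {len(rep)} unique clonotypes -> {len(table)} clusters\n")
print(table.to_frame().round(3).to_string(index=False))
print("\nEach row is one cluster; node_count is its size, the count columns "
      "sum clone abundances, and the remaining columns are graph statistics "
      "of the induced subgraph.")
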