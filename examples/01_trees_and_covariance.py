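"""Trees: parsing, pruning, MCC summarization and Pagel transforms.

Builds a tiny tree sample, summarizes it to a maximum-clade-credibility tree,
and shows how the lambda transform reshapes the phylogenetic covariance that
every downstream likelihood consumes.
"""

import numpy as np

import sharkpcm as sp

# three candidate topologies for the same five species
sample = [
    sp.parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);"),
    sp.parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);"),
    sp.parse_newick("(((A:1,C:1):1,B:2):1,(D:1.5,E:1.5):1.5);"),
]
res = sp.mcc_tree(sample)
print("MCC tree:", sp.write_newick(res.tree))
print(f"log clade credibility: {res.log_credibility:.3f}")
# the AB clade appears in 2 of 3 trees; its frequency drives the choice
ab = frozenset({"A", "B"})
print(f"frequency of the (A,B) clade: {res.clade_frequencies[ab]:.2f}")

cov = sp.phylo_covariance(res.tree, order=["A", "B", "C", "D", "E"])
print("\nshared-path covariance (diagonal = tip depths):")
print(np.round(cov.matrix, 2))

# lambda = 0 erases shared history: a star phylogeny
star = sp.transform_tree(cov, "lambda", 0.0)
print("\nafter lambda = 0 every off-diagonal entry is 0 (independent species):")
print(np.round(star.matrix, 2))

pruned = sp.prune(res.tree, ["A", "C", "E"])
print("\npruned to {A, C, E} (stem lengths folded in):", sp.write_newick(pruned))
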