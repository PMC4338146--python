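"""Spearman-distance neighbor-joining dendrogram of the 25 tissues."""
from ishatlas import (
    encode_ordinal,
    generate_annotation_matrix,
    is_monophyletic_unrooted,
    table1_config,
    tissue_tree,
)
from ishatlas.reference import DENDROGRAM_BRANCHES

matrix = generate_annotation_matrix(table1_config(seed=1, n_genes=2000))
tree, dist = tissue_tree(encode_ordinal(matrix))

print("closest tissue pairs (1 - Spearman rho):")
frame = dist.to_frame()
pairs = (
    frame.stack()
    .loc[lambda s: s > 0]
    .sort_values()
    .iloc[:6:2]  # symmetric matrix: every pair appears twice
)
for (a, b), d in pairs.items():
    print(f"  {a} -- {b}: {d:.3f}")

for label, members in DENDROGRAM_BRANCHES.items():
    mono = is_monophyletic_unrooted(tree, members)
    print(f"branch {label} ({len(members)} tissues) monophyletic: {mono}")

print()
print(tree.to_newick()[:100] + "...")
print(
    "\nTissues sharing a planted latent factor (emulating common embryonic\n"
    "origin or function) cluster into the same branch of the unrooted tree."
)
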