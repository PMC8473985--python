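"""Extract orthogroups from one unrooted gene tree.

Builds a small subfamily gene tree (three bat species, one species-specific
duplication), runs the unrooted orthology extraction and prints the clusters.
"""

import orthodiv as od

NEWICK = (
    "(((Ccas_g1:1,Ccas_g2:1)99:1,(Csow_g1:1,Cper_g1:1)80:1)75:1,"
    "(Ccas_g3:1,(Csow_g2:1,Cper_g2:1)88:1)90:1);"
)

gene_tree = od.parse_gene_tree(NEWICK, subfamily="OR10")
ogset = od.extract_orthogroups(gene_tree, min_taxa=1, in_paralogs=True)

print(f"{len(gene_tree.leaves)} genes from {len(gene_tree.species)} species")
for i, og in enumerate(sorted(ogset, key=lambda o: min(o.members)), start=1):
    clusters = [sorted(c) for c in og.in_paralog_clusters]
    print(f"OG{i:04d}: {sorted(og.members)}  in-paralog clusters: {clusters or '-'}")

# Each orthogroup holds orthologs plus same-species (in-paralog) duplicates;
# genes split off by a pre-speciation duplication land in separate orthogroups.
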