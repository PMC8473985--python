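"""Phylogenetically corrected comparison of species-level diversity.

Fits the Gaussian mixed model to per-(subfamily, species) H' values with the
species relatedness matrix from the dated species tree, then compares species
marginals by 50% credible intervals: disjoint intervals = notable difference.
"""

import orthodiv as od
from orthodiv.simulate import BDParams, DEFAULT_SPECIES_TREE

specs = [
    (f"SF{i:02d}", 20, BDParams(birth=0.02, death=0.01, rate_multipliers={"Ccas": 3.0}))
    for i in range(1, 9)
]
dataset = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=5)
by_sub = od.species_diversity(dataset.abundance, scope="by_subfamily")

tree = od.read_species_tree(DEFAULT_SPECIES_TREE)
print("relatedness matrix:")
print(od.relatedness_matrix(tree, sorted(dataset.species)).round(3))

config = od.FitConfig(iterations=30_000, thin=10, burn_in_samples=500, seed=6)
fit = od.fit_phylo_lmm(by_sub, tree, config)

for sp in fit.species_levels:
    col = fit.draws[f"species_{sp}"]
    print(f"{sp}: posterior diversity {col.median():.3f} "
          f"[{col.quantile(0.25):.3f}, {col.quantile(0.75):.3f}] (50% interval)")

comparison = od.compare_groups(fit, groups="species", interval=0.5)
print("\npairwise comparison (notable = disjoint 50% intervals):")
print(comparison[["group_a", "group_b", "notable"]].to_string(index=False))
# The specialist lineage (3x duplication/loss) shows notably lower diversity.
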