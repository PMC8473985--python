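"""Posterior-predictive redundancy threshold for orthogroup gene counts.

Fits the overdispersed Poisson model to simulated per-orthogroup,
per-species counts and derives the integer outlier threshold: orthogroups
where one species holds that many genes or more show exceptional redundancy.
"""

import orthodiv as od
from orthodiv.bayes import observations_from_abundance, posterior_predictive_threshold
from orthodiv.simulate import BDParams, DEFAULT_SPECIES_TREE

specs = [
    (f"SF{i:02d}", 25, BDParams(birth=0.02, death=0.01, rate_multipliers={"Ccas": 3.0}))
    for i in range(1, 7)
]
dataset = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=8)
obs = observations_from_abundance(dataset.abundance)
print(f"{len(obs)} observed (orthogroup, species) cells, "
      f"mean count {obs['count'].mean():.2f}")

config = od.FitConfig(iterations=30_000, thin=10, burn_in_samples=500, seed=2)
fit = od.fit_poisson_glmm(obs, config)
th = posterior_predictive_threshold(fit, seed=3)

print(f"predictive 95% upper limit: {th.mean_upper:.2f} (+/- {th.sd_upper:.2f})")
print(f"redundancy threshold: {th.threshold} or more genes of one species")

flags = od.flag_redundant_orthogroups(dataset.abundance, th.threshold)
print(f"\n{len(flags)} exceptional (orthogroup, species) cells; top 5:")
print(flags.head(5).to_string(index=False))
# With an elevated duplication regime on Ccas, most flags are Ccas expansions.
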