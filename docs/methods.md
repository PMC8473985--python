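# Methods

This note records the models, algorithms and numerical choices behind
`orthodiv`, and what the synthetic-data tests do and do not demonstrate.

## Unrooted orthology extraction

**Model.** An orthogroup is the set of genes descending from one ancestral
gene in the common ancestor of the species compared: orthologs plus
lineage-specific (in-paralog) duplicates. Duplicates that arose before a
speciation (out-paralogs) belong to different orthogroups. On an *unrooted*
gene tree no duplication/speciation labelling is available, so orthogroups
are read off the branch structure alone.

**Candidate pool.** Every internal branch induces a bipartition (split) of
the leaves; both sides of every internal split are candidates, plus the
whole leaf set (which admits a pure single-species expansion — an entire
subfamily tree of in-paralogs — as one orthogroup). Complements of pendant
branches are deliberately *not* candidates: admitting them lets a
three-species side assembled across the deepest split outrank the two clean
two-species orthogroups it straddles, which contradicts how branch-based
orthology is meant to read an unrooted tree.

**Validity.** Within a candidate, a species' genes collapse to a single
in-paralog unit only if they are monophyletic *in the candidate's subtree
rooted at the branch that induced it*. Algebraically this reduces to: a
same-species group collapses iff it equals the whole candidate or is itself
one side of a full-tree split. (The reduction holds because a clade of the
rooted side is exactly the far side of some branch interior to the side.)
A candidate is valid when, after collapsing, no species occurs twice and at
least `min_taxa` (default 1) species remain. Under a hard polytomy a group
that no single branch separates is not collapsed — multifurcations are
treated as genuine uncertainty, not resolved silently.

**Assembly.** Valid candidates are ranked by species count (descending),
then member count (descending), then the sorted member-label tuple, and
accepted greedily subject to disjointness; uncovered leaves become singleton
orthogroups. The full-tuple tie-break makes the partition a deterministic
function of the tree alone, independent of leaf input order and process hash
state. Branch supports (auto-detected percent or fraction scale, stored on
[0,1]) can gate candidates via `min_support`; the default 0 applies no
filter. The rooting outgroup (matched by a configurable label pattern) is
pruned before extraction: it is a rooting device, not a repertoire member.

An independent brute-force oracle (graph edge-cuts, rooted DFS monophyly,
identical ranking) cross-checks the implementation on hundreds of random
trees in the test suite.

## Shannon diversity levels

Subfamily = community, orthogroup = site, abundance = gene copies of a
species in an orthogroup. `shannon` computes H′ = −Σ pᵢ ln pᵢ (nats) over the
positive entries of a count vector. Three levels:

* **orthogroup** — over species' counts within one orthogroup (≤ ln N for
  N species); 0 means a species-exclusive orthogroup;
* **subfamily × species** — one species' counts across a subfamily's
  orthogroups, the response variable of the comparison model;
* **pooled per species** — across all orthogroups; bounded by ln(occupied
  orthogroups), with equality exactly for a single-copy repertoire. This is
  the repertoire-wide value compared among species.

Rows where a species has zero count are excluded from that species' vector;
the value is identical under the 0·ln 0 := 0 convention, the exclusion is
just explicit. Species with no genes are omitted with a warning rather than
given an undefined entropy.

## Poisson count model and redundancy threshold

For observed cells (count ≥ 1; a species absent from an orthogroup
contributes no receptor, and structural zeros can be included via a toggle):

    y_j ~ Poisson(exp(b0 + b_species(j) + u_subfamily(j) + e_j))
    u_k ~ N(0, s2_u),   e_j ~ N(0, s2_e)

`e` is observation-level additive overdispersion, absorbing residual
variance from incomplete sequencing or gene-tree error. Priors are weakly
informative: N(0, 100) on fixed effects, inverse-gamma(0.001, 0.001) on both
variance components. The sampler is Metropolis-within-Gibbs: vectorised
per-observation random-walk updates for `e`, scalar random-walk updates for
the intercept, species contrasts (first species in sorted order is the
reference, pinned at 0) and subfamily effects, conjugate inverse-gamma draws
for the variances. Proposal scales adapt toward ~35% acceptance during
burn-in only and freeze afterwards, so retained draws come from a
fixed-kernel chain; a fixed seed reproduces draws bit-exactly. An effective
sample size check (arviz) warns — never silently passes — when any
parameter's ESS falls below the configured floor.

The default protocol is 5 million iterations thinned every 500 with the
first 1000 *retained samples* discarded (10,000 retained → 9,000 kept);
"burn-in" counts samples, not iterations, and is configurable. Analyses in
this repository use shorter chains (50k iterations thinned 10) chosen so the
recovery checks pass with comfortable ESS at desk scale.

**Threshold.** For each kept draw, one count is simulated per observed
design cell with `e` redrawn, and the empirical q-quantile (q = 0.95;
smallest count with CDF ≥ q) of that simulated marginal is the draw's upper
limit. Reported: posterior mean ± sd of the upper limit, a pooled-sample
variant (quantile over all draws' simulations — both conventions are
computed since either reading is defensible), and the integer threshold =
smallest integer strictly greater than the mean upper limit (3.24 → 4; an
exact 3.0 → 4). With a degenerate posterior and no overdispersion this
reproduces the analytic Poisson quantile, the test suite's closed-form
anchor. Cells at or above the threshold are flagged as exceptional
redundancy.

## Phylogenetically corrected diversity model

Subfamily × species H′ values:

    H_ij = mu + a_species(i) + b_subfamily(j) + eps_ij
    a ~ N(0, s2_a · C),  b ~ N(0, s2_b · I),  eps ~ N(0, s2_eps)

C is the species relatedness matrix: shared root-to-MRCA path length,
divided by the maximum tip depth (correlation scaling; diagonal 1 for an
ultrametric tree). Branch-length units therefore cancel. The sampler is full
conjugate Gibbs (joint multivariate-normal update for `a` using C⁻¹). A
singular or non-positive-definite C raises with a jitter suggestion; fewer
than two subfamilies is an error because nothing then separates subfamily
effects from residual. Group marginals are reported as mu + a_i (species)
and mu + b_j (subfamily); two groups are *notable* when their central 50%
credible intervals around the median are disjoint. Widening the interval can
only remove notability (nested intervals), which the tests assert.

With C = I the model reduces to an ordinary two-way random-effects model;
the test suite cross-checks posterior means against an independently coded
scalar-update Gibbs sampler for that reduced model.

## Sequence intactness filter

A receptor sequence is intact iff it is ≥ 650 bp (the shortest length
compatible with a complete seven-transmembrane domain) *and* some reading
frame on either strand carries a start-to-stop ORF spanning ≥ 650 bp
(an ORF running off the contig end is accepted as open-ended). Otherwise:
`too_short` (raw length < 650 bp, regardless of ORF content — raw length,
not ORF span, is the length criterion), else `premature_stop` when the best
ORF is stop-terminated short of 650 bp, else `frameshift`. Without a
reference genome, frameshift detection on assembled contigs is
under-determined; this operational rule (long enough, but no frame sustains
650 bp and no premature stop terminates the best ORF) is a testable proxy,
not reference-based indel calling. Both strands are scanned because
assembled contigs have arbitrary orientation. Exact duplicates (identical
nucleotide strings; reverse complements are *not* duplicates) collapse to
the first occurrence. The filter's classes partition the input and the
filter is idempotent.

## Birth–death simulator

Gene families evolve along an ultrametric species tree by an exact
event-driven (Gillespie) linear birth–death process: per extant copy,
duplication at rate λ·m and loss at rate μ·m per time unit, with waiting
times drawn exponentially per branch; copies bifurcate with the species tree
at speciation nodes. Rate multipliers `m` apply on terminal branches (keyed
by species) and default to 1 elsewhere — the minimal way to emulate a
lineage-specific duplication regime such as a dietary specialist's. The
event-driven formulation keeps the closed-form expectation
E[N_T] = n0·e^{(λ−μ)T} exact, which the tests verify by simulation.

**Ground-truth orthogroups** come from event bookkeeping: a duplication on
an internal species-tree branch founds a new orthogroup for one daughter
(out-paralogs); a duplication on a terminal branch keeps both daughters in
the same orthogroup as in-paralogs. Same-species groups of size ≥ 2 within a
truth orthogroup are exactly the terminal-branch duplication clusters.

**Default study conditions.** Three congeneric species on
`((Csow:6,Cper:6):6,Ccas:12);` (a ~12-unit-deep recent radiation, specialist
lineage diverging first), 12 subfamilies × 30 founding families, birth 0.02
and death 0.01 per gene per time unit, 3× multiplier on the specialist.
These rates give mostly single-copy orthogroups with occasional small
expansions (mean count ~1.3 per occupied cell) — the regime in which the
redundancy threshold resolves to 4, matching the magnitude observed in real
receptor repertoires of recently diverged species. Repertoire sizes here
(~400 orthogroups, ~1400 genes) are a deliberate scale-down of a real
repertoire (~1000 orthogroups); all statistics used are intensive, not
extensive, so the scale-down changes Monte-Carlo error, not structure.

**What the simulator does not emulate:** sequence evolution on gene trees
(trees are consumed directly; sequence defects are injected into template
FASTA), gene conversion, horizontal transfer, within-branch rate
heterogeneity, assembly artefacts, and allelic variation masquerading as
in-paralogy. Passing tests therefore demonstrate correctness of the
*methods* under the stated generative model, not robustness to every
real-data pathology.

Other generators: `simulate_glmm_counts` draws counts from the exact count
model (zero-truncated by default to match the observed-cells convention;
untruncated via toggle, which parameter-recovery tests use so the data come
from the model being fitted — fitting untruncated likelihoods to truncated
data at these intensities would bias the intercept upward);
`inject_sequence_defects` truncates, substitutes a stop at codon 30, or
deletes a base early in the ORF (early, so neither the in-frame prefix nor
the shifted tail can reach 650 bp; the injection is verified against the
classifier and retried within the ORF if an internal ATG rescues a long
frame).

## Pipeline and reproducibility

`run_pipeline` chains filter → orthogroups → abundance → diversity →
threshold → comparison from one config (YAML or dataclass). All randomness
derives from a single root seed through named `SeedSequence` substreams; no
output embeds timestamps, so a rerun with the same config is byte-identical,
and `manifest.json` (inputs, seed, parameter hash, version) suffices to
recompute every number. Stage failures abort with the stage name and the
offending input. The CLI (`orthodiv filter|orthogroups|diversity|threshold|
compare|simulate|run`) is a thin wrapper over these library functions.

## Known limitations

* The greedy-maximal assembly is a deterministic reconstruction of
  branch-based unrooted orthology; other maximality resolutions exist, and
  on real deposited trees results should be compared, not assumed identical.
* No bootstrap-support filter is applied by default (`min_support = 0`).
* The count model fits observed cells without modelling zero-truncation;
  at intensities near 1 the intercept is therefore a rate *given presence*.
* No model selection (Poisson vs negative-binomial), no WAIC/LOO, and only
  an ESS floor as convergence diagnostic; single-chain sampling.
* Shannon indices only — no rarefaction, Simpson or Hill-number
  generalisations.
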