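"""Synthetic data with known truth: birth-death gene families, overdispersed
count designs, and defect-injected receptor sequences.

Gene families evolve along a dated (ultrametric) species tree under a linear
birth-death process: each extant gene copy duplicates at rate ``birth * m``
and is lost at rate ``death * m`` per time unit, simulated event-by-event
(Gillespie) on every species-tree branch, with copies bifurcating alongside
the species tree at speciation nodes. Per-species rate multipliers ``m``
apply on terminal branches, which is how a dietary-specialist lineage with an
elevated duplication regime is emulated; internal branches use the base
rates.

Ground-truth orthogroups come from event bookkeeping: a duplication on an
*internal* species-tree branch splits the descendant copies into different
orthogroups (out-paralogs), while a duplication on a terminal branch leaves
both copies in the same orthogroup as species-specific in-paralogs. Defaults
approximate a recent radiation of three congeneric species (root age ~12 time
units, per-copy duplication rate 0.02 and loss rate 0.01 per unit), giving
mostly single-copy orthogroups with occasional small expansions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import AbundanceMatrix, build_abundance_matrix
from .orthology import Orthogroup, OrthogroupSet
from .seqfilter import classify_sequence, locate_best_orf, _revcomp
from .treeio import GeneTree, gene_tree_from_dendropy, read_species_tree

__all__ = [
    "BDParams",
    "SimulatedFamily",
    "RepertoireDataset",
    "simulate_gene_family",
    "simulate_repertoire",
    "simulate_glmm_counts",
    "random_intact_sequence",
    "make_intact_repertoire",
    "inject_sequence_defects",
    "DEFAULT_SPECIES_TREE",
]

# three congeneric species, specialist lineage diverging first, root at 12
DEFAULT_SPECIES_TREE = "((Csow:6.0,Cper:6.0):6.0,Ccas:12.0);"


@dataclass(frozen=True)
class BDParams:
    """Birth-death rates for one gene family (per gene copy per time unit)."""

    birth: float = 0.02
    death: float = 0.01
    n_root: int = 1
    rate_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be nonnegative")
        if self.n_root < 1:
            raise ValueError("n_root must be >= 1")
        if any(m < 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be >= 0")


@dataclass
class SimulatedFamily:
    """One simulated gene family with event-bookkeeping ground truth."""

    gene_tree: GeneTree | None  # None when every copy was lost
    true_orthogroups: OrthogroupSet
    counts: dict[str, int]
    events: list[tuple[str, float, str]]  # (species-tree branch, time-on-branch, kind)
    subfamily: str | None = None


class _SimState:
    def __init__(self, rng: np.random.Generator, tns: dendropy.TaxonNamespace):
        self.rng = rng
        self.tns = tns
        self.truth: dict[int, list[str]] = {}
        self.events: list[tuple[str, float, str]] = []
        self.leaf_counters: dict[str, int] = {}
        self.next_og = 0

    def new_og(self) -> int:
        og = self.next_og
        self.next_og += 1
        self.truth[og] = []
        return og

    def new_leaf(self, species: str, og: int) -> dendropy.Node:
        self.leaf_counters[species] = self.leaf_counters.get(species, 0) + 1
        label = f"{species}_g{self.leaf_counters[species]}"
        node = dendropy.Node()
        node.taxon = self.tns.new_taxon(label)
        self.truth[og].append(label)
        return node


def _branch_label(sp_node: dendropy.Node) -> str:
    if sp_node.is_leaf():
        return sp_node.taxon.label
    return "node" + "+".join(sorted(lf.taxon.label for lf in sp_node.leaf_iter()))


def _sim_lineage(
    sp_node: dendropy.Node,
    t_pos: float,
    og: int,
    params: BDParams,
    state: _SimState,
) -> dendropy.Node | None:
    """Evolve one gene lineage from position ``t_pos`` on the branch above
    ``sp_node``; returns the surviving gene subtree (edge.length spans from
    t_pos to the subtree root's event) or None on extinction."""
    L = sp_node.edge.length or 0.0
    terminal = sp_node.is_leaf()
    m = params.rate_multipliers.get(sp_node.taxon.label, 1.0) if terminal else 1.0
    lam, mu = params.birth * m, params.death * m
    rate = lam + mu
    wait = state.rng.exponential(1.0 / rate) if rate > 0 else math.inf
    if t_pos + wait < L:
        t_ev = t_pos + wait
        if state.rng.uniform() < (mu / rate if rate > 0 else 0.0):
            state.events.append((_branch_label(sp_node), t_ev, "loss"))
            return None
        state.events.append((_branch_label(sp_node), t_ev, "duplication"))
        # a duplication on an internal branch founds a new orthogroup
        og_b = og if terminal else state.new_og()
        child_a = _sim_lineage(sp_node, t_ev, og, params, state)
        child_b = _sim_lineage(sp_node, t_ev, og_b, params, state)
        live = [c for c in (child_a, child_b) if c is not None]
        if not live:
            return None
        if len(live) == 1:
            live[0].edge.length = (live[0].edge.length or 0.0) + (t_ev - t_pos)
            return live[0]
        node = dendropy.Node()
        node.edge.length = t_ev - t_pos
        for c in live:
            node.add_child(c)
        return node
    # lineage reaches the bottom of this species-tree branch
    if terminal:
        leaf = state.new_leaf(sp_node.taxon.label, og)
        leaf.edge.length = L - t_pos
        return leaf
    subtrees = [
        _sim_lineage(child, 0.0, og, params, state)
        for child in sp_node.child_nodes()
    ]
    live = [s for s in subtrees if s is not None]
    if not live:
        return None
    if len(live) == 1:
        live[0].edge.length = (live[0].edge.length or 0.0) + (L - t_pos)
        return live[0]
    node = dendropy.Node()
    node.edge.length = L - t_pos
    for s in live:
        node.add_child(s)
    return node


def simulate_gene_family(
    species_tree,
    params: BDParams,
    rng: np.random.Generator | int | None = None,
    subfamily: str | None = None,
) -> SimulatedFamily:
    """Simulate one gene family along an ultrametric species tree.

    ``species_tree`` may be a dendropy tree, a newick string or a path. With
    birth = death = 0 the result is exactly ``n_root`` single-copy
    orthogroups, one gene per extant species each. If every copy dies the
    family is empty (``gene_tree`` None, all counts zero) — a valid outcome.
    """
    if not isinstance(species_tree, dendropy.Tree):
        species_tree = read_species_tree(species_tree, ultrametric_rtol=1e-6)
    else:
        # verify ultrametricity of the provided tree
        read_species_tree(
            species_tree.as_string(schema="newick", unquoted_underscores=True),
            ultrametric_rtol=1e-6,
        )
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    species = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())

    tns = dendropy.TaxonNamespace()
    state = _SimState(rng, tns)
    root_subtrees: list[dendropy.Node] = []
    for _ in range(params.n_root):
        og = state.new_og()
        subtrees = [
            _sim_lineage(child, 0.0, og, params, state)
            for child in species_tree.seed_node.child_nodes()
        ]
        live = [s for s in subtrees if s is not None]
        if len(live) == 1:
            root_subtrees.append(live[0])
        elif len(live) > 1:
            node = dendropy.Node()
            node.edge.length = 0.0
            for s in live:
                node.add_child(s)
            root_subtrees.append(node)

    counts = {sp: 0 for sp in species}
    for labels in state.truth.values():
        for label in labels:
            counts[label.split("_", 1)[0]] += 1

    if not root_subtrees:
        gene_tree = None
    else:
        if len(root_subtrees) == 1:
            seed = root_subtrees[0]
        else:
            seed = dendropy.Node()
            for s in root_subtrees:
                s.edge.length = s.edge.length or 0.0
                seed.add_child(s)
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = seed
        gene_tree = gene_tree_from_dendropy(tree, subfamily=subfamily)

    orthogroups = []
    for og_id in sorted(state.truth):
        labels = state.truth[og_id]
        if not labels:
            continue
        members = frozenset(labels)
        by_species: dict[str, set[str]] = {}
        for label in labels:
            by_species.setdefault(label.split("_", 1)[0], set()).add(label)
        orthogroups.append(
            Orthogroup(
                members=members,
                species_present=frozenset(by_species),
                in_paralog_clusters=[
                    frozenset(v) for _, v in sorted(by_species.items()) if len(v) > 1
                ],
                subfamily=subfamily,
                species_by_member={l: l.split("_", 1)[0] for l in labels},
            )
        )
    truth_set = OrthogroupSet(orthogroups=orthogroups, subfamily=subfamily)
    return SimulatedFamily(
        gene_tree=gene_tree,
        true_orthogroups=truth_set,
        counts=counts,
        events=state.events,
        subfamily=subfamily,
    )


@dataclass
class RepertoireDataset:
    """A multi-subfamily simulated repertoire plus ground truth."""

    families: dict[str, SimulatedFamily]
    species: list[str]
    abundance: AbundanceMatrix  # truth-based orthogroup x species counts

    @property
    def gene_trees(self) -> dict[str, GeneTree]:
        return {
            name: fam.gene_tree
            for name, fam in self.families.items()
            if fam.gene_tree is not None
        }

    @property
    def truth(self) -> dict[str, OrthogroupSet]:
        return {name: fam.true_orthogroups for name, fam in self.families.items()}


def simulate_repertoire(
    species_tree,
    subfamily_specs: list[tuple[str, int, BDParams]],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> RepertoireDataset:
    """Simulate independent gene families per subfamily.

    Each (name, n_families, params) spec yields one gene tree holding
    ``n_families`` independently seeded root genes (the subfamily's founding
    paralogs). Randomness flows through named substreams of ``seed``, so a
    fixed seed reproduces the dataset byte-for-byte. With ``out_dir`` the
    dataset is written in the formats the analysis pipeline consumes:
    per-subfamily newick, a subfamily registry TSV, truth cluster lists and
    the truth abundance matrix.
    """
    if not subfamily_specs:
        raise ValueError("at least one subfamily spec required")
    if not isinstance(species_tree, dendropy.Tree):
        species_tree = read_species_tree(species_tree, ultrametric_rtol=1e-6)
    species = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())
    names = [name for name, _, _ in subfamily_specs]
    if len(set(names)) != len(names):
        raise ValueError("subfamily names must be unique")

    root_ss = np.random.SeedSequence(seed)
    streams = root_ss.spawn(len(subfamily_specs))
    families: dict[str, SimulatedFamily] = {}
    for (name, n_fam, params), ss in zip(subfamily_specs, streams):
        fam_params = BDParams(
            birth=params.birth,
            death=params.death,
            n_root=n_fam * params.n_root,
            rate_multipliers=dict(params.rate_multipliers),
        )
        families[name] = simulate_gene_family(
            species_tree, fam_params, np.random.default_rng(ss), subfamily=name
        )

    truth_sets = [fam.true_orthogroups for fam in families.values()]
    abundance = build_abundance_matrix(truth_sets, species)
    dataset = RepertoireDataset(families=families, species=species, abundance=abundance)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        registry_rows = []
        for name in sorted(families):
            gt = families[name].gene_tree
            if gt is None or len(gt.leaves) < 2:
                continue  # empty/singleton families are unanalysable as trees
            tree_path = out / f"{name}.nwk"
            tree_path.write_text(gt.as_newick() + "\n")
            registry_rows.append(f"{name}\t{name}.nwk\n")
        (out / "registry.tsv").write_text("".join(registry_rows))
        from .treeio import write_orthogroup_clusters

        write_orthogroup_clusters(truth_sets, out / "truth_clusters.tsv")
        abundance.to_tsv(out / "truth_abundance.tsv")
    return dataset


def simulate_glmm_counts(
    n_orthogroups: int,
    species: list[str],
    subfamilies: list[str],
    beta0: float,
    species_effects: dict[str, float] | None = None,
    sigma2_u: float = 0.0,
    sigma2_e: float = 0.0,
    seed: int = 0,
    zero_truncated: bool = True,
) -> pd.DataFrame:
    """Counts from the overdispersed Poisson GLMM with known parameters.

    Orthogroups are assigned to subfamilies round-robin; every (orthogroup,
    species) cell receives a count. ``zero_truncated=True`` conditions each
    cell on being observed (count >= 1), matching the observed-cells
    convention of real repertoires; with ``False`` counts come from the
    untruncated model itself (for parameter-recovery checks).
    """
    if n_orthogroups < 1 or not species or not subfamilies:
        raise ValueError("need at least one orthogroup, species and subfamily")
    rng = np.random.default_rng(seed)
    species_effects = species_effects or {}
    u = {k: rng.normal(0.0, np.sqrt(sigma2_u)) if sigma2_u > 0 else 0.0 for k in subfamilies}
    rows = []
    for g in range(n_orthogroups):
        subfam = subfamilies[g % len(subfamilies)]
        for sp in species:
            eta = beta0 + species_effects.get(sp, 0.0) + u[subfam]
            if sigma2_e > 0:
                eta += rng.normal(0.0, np.sqrt(sigma2_e))
            lam = np.exp(eta)
            if zero_truncated:
                lo = np.exp(-lam)
                uval = rng.uniform(lo, 1.0)
                count = int(stats.poisson.ppf(uval, lam))
                count = max(count, 1)
            else:
                count = int(rng.poisson(lam))
            rows.append(
                {
                    "orthogroup": f"OG{g + 1:04d}",
                    "species": sp,
                    "subfamily": subfam,
                    "count": count,
                }
            )
    return pd.DataFrame(rows, columns=["orthogroup", "species", "subfamily", "count"])


# body codons: no stops (uninterrupted frame) and no ATG (a frameshift must
# not leave a downstream in-frame restart that would still read as intact)
_BODY_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA", "ATG"}
]


def random_intact_sequence(rng: np.random.Generator, n_codons: int = 310) -> str:
    """An intact receptor-like sequence: ATG, ``n_codons`` sense codons, TAA."""
    if n_codons * 3 + 6 < 650:
        raise ValueError("n_codons too small to produce an intact (>=650 bp) ORF")
    body = "".join(rng.choice(_BODY_CODONS, size=n_codons))
    return "ATG" + body + "TAA"


def make_intact_repertoire(
    n: int, rng: np.random.Generator | int | None = None, prefix: str = "seq"
) -> list[SeqRecord]:
    """n distinct intact sequences as Biopython records."""
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    records = []
    for i in range(n):
        seq = random_intact_sequence(rng)
        records.append(SeqRecord(Seq(seq), id=f"{prefix}{i + 1:03d}", description=""))
    return records


def inject_sequence_defects(
    records: list[SeqRecord],
    defects: dict[str, int],
    seed: int = 0,
    truncate_to: int = 600,
    stop_codon_index: int = 30,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Inject known pseudogenising defects into intact sequences.

    ``defects`` maps defect kind (``too_short``, ``premature_stop``,
    ``frameshift``) to the number of sequences to hit; targets are chosen
    without replacement in record order by a seeded draw. Returns the
    modified records and a truth table (id, defect, expected_class). Inputs
    must be intact; a defect that cannot be applied (sequence/ORF too short)
    raises.
    """
    unknown = set(defects) - {"too_short", "premature_stop", "frameshift"}
    if unknown:
        raise ValueError(f"unknown defect kinds: {sorted(unknown)}")
    total = sum(defects.values())
    if total > len(records):
        raise ValueError(f"{total} defects requested for {len(records)} sequences")
    for rec in records:
        cls, _ = classify_sequence(str(rec.seq))
        if cls != "intact":
            raise ValueError(f"input sequence {rec.id!r} is not intact")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    assignment: dict[int, str] = {}
    cursor = 0
    for kind in ("too_short", "premature_stop", "frameshift"):
        for _ in range(defects.get(kind, 0)):
            assignment[order[cursor]] = kind
            cursor += 1

    out: list[SeqRecord] = []
    truth_rows = []
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper()
        kind = assignment.get(i)
        if kind is None:
            out.append(rec)
            truth_rows.append({"id": rec.id, "defect": "none", "expected_class": "intact"})
            continue
        if kind == "too_short":
            if len(seq) <= truncate_to:
                raise ValueError(f"{rec.id}: sequence too short to truncate to {truncate_to}")
            new_seq = seq[:truncate_to]
        else:
            loc = locate_best_orf(seq)
            if loc.span // 3 <= stop_codon_index + 1:
                raise ValueError(f"{rec.id}: ORF too short to modify at codon {stop_codon_index}")
            work = seq if loc.strand == +1 else _revcomp(seq)
            if kind == "premature_stop":
                pos = loc.offset + (loc.start_codon_index + stop_codon_index) * 3
                new_work = work[:pos] + "TAA" + work[pos + 3 :]
            else:
                # frameshift: delete one base early in the ORF, so neither the
                # in-frame prefix nor the shifted downstream can reach 650 bp;
                # verified against the classifier (an internal in-frame ATG can
                # otherwise restart a long ORF) with a few retries
                orf_start = loc.offset + loc.start_codon_index * 3
                new_work = None
                for _ in range(20):
                    del_pos = orf_start + 3 + int(rng.integers(0, min(loc.span - 6, 150)))
                    attempt = work[:del_pos] + work[del_pos + 1 :]
                    cand = attempt if loc.strand == +1 else _revcomp(attempt)
                    if classify_sequence(cand)[0] == "pseudogene":
                        new_work = attempt
                        break
                if new_work is None:
                    raise ValueError(
                        f"{rec.id}: could not pseudogenise by single-base deletion"
                    )
            new_seq = new_work if loc.strand == +1 else _revcomp(new_work)
        out.append(SeqRecord(Seq(new_seq), id=rec.id, description=rec.description))
        expected = "pseudogene"
        truth_rows.append({"id": rec.id, "defect": kind, "expected_class": expected})
    truth = pd.DataFrame(truth_rows, columns=["id", "defect", "expected_class"])
    return out, truth
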