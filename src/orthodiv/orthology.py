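"""Unrooted phylogenetic orthology: orthogroup extraction from gene trees.

An orthogroup is a set of genes descended from a single ancestral gene in the
common ancestor of the species compared: orthologs plus lineage-specific
(in-paralog) duplicates. On an *unrooted* gene tree, every branch induces a
bipartition (split) of the leaves, and either side of an internal split is a
candidate orthogroup. A candidate is valid when, after collapsing each
species' leaves that are monophyletic *within the candidate* into single
in-paralog units, no species occurs more than once and at least ``min_taxa``
species remain. Valid candidates are assembled into a partition of the leaf
set by a deterministic greedy-maximal rule; anything left over becomes a
singleton orthogroup.

The candidate pool is the sides of internal (nontrivial) splits plus the
whole leaf set — the latter admits pure species-specific expansions, where an
entire single-species tree is one orthogroup of in-paralogs (the exceptional
redundancy signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .treeio import GeneTree

__all__ = [
    "Split",
    "Orthogroup",
    "OrthogroupSet",
    "enumerate_splits",
    "candidate_valid",
    "extract_orthogroups",
    "count_in_paralogs",
]


@dataclass(frozen=True)
class Split:
    """A bipartition of the leaf-label set induced by one branch."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    support: float

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a split must be nonempty")
        if self.side_a & self.side_b:
            raise ValueError("split sides must be disjoint")

    @property
    def is_pendant(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1

    def key(self) -> frozenset[frozenset[str]]:
        return frozenset((self.side_a, self.side_b))


@dataclass
class Orthogroup:
    """One orthogroup: members plus collapsed same-species in-paralog units."""

    members: frozenset[str]
    species_present: frozenset[str]
    in_paralog_clusters: list[frozenset[str]] = field(default_factory=list)
    subfamily: str | None = None
    species_by_member: dict[str, str] = field(default_factory=dict)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for member in self.members:
            sp = self.species_by_member[member]
            counts[sp] = counts.get(sp, 0) + 1
        return counts


@dataclass
class OrthogroupSet:
    """A partition of a gene tree's leaves into orthogroups."""

    orthogroups: list[Orthogroup]
    subfamily: str | None = None
    min_taxa: int = 1
    min_support: float = 0.0
    in_paralogs: bool = True

    def __iter__(self):
        return iter(self.orthogroups)

    def __len__(self) -> int:
        return len(self.orthogroups)

    @property
    def members(self) -> frozenset[str]:
        out: set[str] = set()
        for og in self.orthogroups:
            out |= og.members
        return frozenset(out)

    def as_partition(self) -> list[frozenset[str]]:
        return [og.members for og in self.orthogroups]


def enumerate_splits(gene_tree: GeneTree) -> list[Split]:
    """One split per branch of the unrooted tree (pendant and internal).

    Pendant splits carry support 1.0; internal splits carry the normalised
    branch support, defaulting to 1.0 where no support was recorded. For a
    binary unrooted tree with n leaves this yields exactly 2n-3 splits.
    """
    tree = gene_tree.tree
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if len(all_leaves) < 2:
        raise ValueError("split enumeration requires at least 2 leaves")
    splits: dict[frozenset[frozenset[str]], Split] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        other = all_leaves - below
        if not other:
            continue
        if len(below) == 1 or len(other) == 1:
            support = 1.0
        else:
            try:
                support = float(nd.label) if nd.label is not None else 1.0
            except ValueError:
                support = 1.0
        sp = Split(side_a=below, side_b=other, support=support)
        splits.setdefault(sp.key(), sp)

    def _order(s: Split) -> tuple:
        small, large = sorted((s.side_a, s.side_b), key=lambda x: (len(x), tuple(sorted(x))))
        return (len(small), tuple(sorted(small)), tuple(sorted(large)))

    return sorted(splits.values(), key=_order)


def _split_sides(splits: list[Split]) -> set[frozenset[str]]:
    sides: set[frozenset[str]] = set()
    for sp in splits:
        sides.add(sp.side_a)
        sides.add(sp.side_b)
    return sides


def candidate_valid(
    side: frozenset[str],
    gene_tree: GeneTree,
    min_taxa: int = 1,
    in_paralogs: bool = True,
    _splits: list[Split] | None = None,
) -> tuple[bool, list[frozenset[str]]]:
    """Test a leaf set as an orthogroup candidate; return collapsed units.

    With ``in_paralogs`` on, each species' leaves within the candidate must be
    monophyletic within the candidate to collapse to a single in-paralog
    unit; validity then requires every species to occur exactly once after
    collapsing and the species count to reach ``min_taxa``. With
    ``in_paralogs`` off, any species occurring twice invalidates the
    candidate.

    Monophyly within a candidate is evaluated with the candidate's subtree
    rooted at the branch that induced it (the unrooted criterion's implicit
    root): a same-species group is a clade there exactly when it is the whole
    candidate or one side of a full-tree split. Under a hard polytomy a group
    that cannot be separated by a single branch is therefore not collapsed.
    """
    if not side:
        raise ValueError("candidate side must be nonempty")
    splits = _splits if _splits is not None else enumerate_splits(gene_tree)
    by_species: dict[str, set[str]] = {}
    for label in side:
        by_species.setdefault(gene_tree.species_of(label), set()).add(label)
    n_species = len(by_species)
    if n_species < min_taxa:
        return False, []
    multi = {sp: frozenset(ls) for sp, ls in by_species.items() if len(ls) > 1}
    if multi and not in_paralogs:
        return False, []
    if multi:
        clade_sides = _split_sides(splits)
        for group in multi.values():
            if group != side and group not in clade_sides:
                return False, []
    units = [frozenset(ls) for _, ls in sorted(by_species.items())]
    return True, units


def extract_orthogroups(
    gene_tree: GeneTree,
    min_taxa: int = 1,
    min_support: float = 0.0,
    in_paralogs: bool = True,
) -> OrthogroupSet:
    """Partition a gene tree's leaves into orthogroups.

    Candidates are both sides of every internal split with support >=
    ``min_support``, plus the full leaf set. Valid candidates are accepted
    greedily in rank order (species count desc, member count desc, smallest
    member label asc), each required to be disjoint from all accepted ones;
    uncovered leaves become singleton orthogroups. The procedure is
    deterministic and independent of leaf input order.
    """
    if min_taxa < 1:
        raise ValueError(f"min_taxa must be >= 1, got {min_taxa}")
    splits = enumerate_splits(gene_tree)
    all_leaves = frozenset(gene_tree.leaf_labels)

    candidate_sides: set[frozenset[str]] = {all_leaves}
    for sp in splits:
        if sp.is_pendant or sp.support < min_support:
            continue
        candidate_sides.add(sp.side_a)
        candidate_sides.add(sp.side_b)

    scored: list[tuple[tuple[int, int, str], frozenset[str], list[frozenset[str]]]] = []
    for side in candidate_sides:
        ok, units = candidate_valid(
            side, gene_tree, min_taxa=min_taxa, in_paralogs=in_paralogs, _splits=splits
        )
        if ok:
            # total order: species count desc, size desc, then the sorted
            # member tuple (lexicographically smallest member first)
            rank = (-len(units), -len(side), tuple(sorted(side)))
            scored.append((rank, side, units))
    scored.sort(key=lambda t: t[0])

    accepted: list[tuple[frozenset[str], list[frozenset[str]]]] = []
    covered: set[str] = set()
    for _, side, units in scored:
        if side & covered:
            continue
        accepted.append((side, units))
        covered |= side

    for label in sorted(all_leaves - covered):
        accepted.append((frozenset({label}), [frozenset({label})]))

    species_by_label = {lf.label: lf.species for lf in gene_tree.leaves}
    orthogroups = []
    for side, units in accepted:
        species = frozenset(species_by_label[l] for l in side)
        orthogroups.append(
            Orthogroup(
                members=side,
                species_present=species,
                in_paralog_clusters=[u for u in units if len(u) > 1],
                subfamily=gene_tree.subfamily,
                species_by_member={l: species_by_label[l] for l in side},
            )
        )
    orthogroups.sort(key=lambda og: min(og.members))
    return OrthogroupSet(
        orthogroups=orthogroups,
        subfamily=gene_tree.subfamily,
        min_taxa=min_taxa,
        min_support=min_support,
        in_paralogs=in_paralogs,
    )


def count_in_paralogs(ogset: OrthogroupSet) -> pd.DataFrame:
    """Long-format per-orthogroup, per-species gene counts.

    Orthogroups are indexed ``OG0001``... in order of smallest member label,
    matching the cluster-list file convention. The table's count total equals
    the number of leaves partitioned.
    """
    ogs = sorted(ogset.orthogroups, key=lambda og: min(og.members))
    rows = []
    for i, og in enumerate(ogs, start=1):
        counts = og.species_counts()
        for sp_name in sorted(counts):
            rows.append(
                {
                    "orthogroup": f"OG{i:04d}",
                    "subfamily": og.subfamily,
                    "species": sp_name,
                    "count": counts[sp_name],
                }
            )
    return pd.DataFrame(rows, columns=["orthogroup", "subfamily", "species", "count"])
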