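"""Reading and writing of gene trees, species trees and tabular artifacts.

Gene trees arrive as newick with leaf labels that bind each gene to a species
(e.g. ``Ccas_g17``: species prefix, separator, gene identifier). The label
convention is declared explicitly rather than guessed, because deposited tree
sets frequently mix conventions. An optional outgroup leaf (a rooting device
such as an ancestral non-OR G-protein-coupled receptor) can be recognised by
pattern and pruned before any downstream analysis.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "GeneLeaf",
    "GeneTree",
    "LabelConvention",
    "TreeParseError",
    "LabelConventionError",
    "parse_gene_tree",
    "gene_tree_from_dendropy",
    "read_species_tree",
    "read_subfamily_registry",
    "write_orthogroup_clusters",
    "read_orthogroup_clusters",
]


class TreeParseError(ValueError):
    """Raised when a newick string cannot be parsed or violates invariants."""


class LabelConventionError(ValueError):
    """Raised when a leaf label does not follow the declared convention."""


@dataclass(frozen=True)
class LabelConvention:
    """How a leaf label encodes (species, gene id).

    Parameters
    ----------
    separator:
        Substring splitting the species prefix from the gene identifier; the
        first occurrence is used (``Ccas_g1_alt`` -> species ``Ccas``, gene
        ``g1_alt``).
    pattern:
        Optional regex with named groups ``species`` and ``gene`` overriding
        the separator rule.
    outgroup_pattern:
        Optional regex; any leaf whose full label matches (``re.search``) is
        flagged as the rooting outgroup and pruned from analysis.
    """

    separator: str = "_"
    pattern: str | None = None
    outgroup_pattern: str | None = None

    def split(self, label: str) -> tuple[str, str]:
        if self.pattern is not None:
            m = re.match(self.pattern, label)
            if not m or "species" not in m.groupdict() or "gene" not in m.groupdict():
                raise LabelConventionError(
                    f"leaf label {label!r} does not match convention pattern {self.pattern!r}"
                )
            return m.group("species"), m.group("gene")
        if self.separator not in label:
            raise LabelConventionError(
                f"leaf label {label!r} lacks the separator {self.separator!r} "
                "required by the species_gene convention"
            )
        species, gene = label.split(self.separator, 1)
        if not species or not gene:
            raise LabelConventionError(
                f"leaf label {label!r} yields an empty species or gene id"
            )
        return species, gene

    def is_outgroup(self, label: str) -> bool:
        return bool(self.outgroup_pattern and re.search(self.outgroup_pattern, label))


DEFAULT_CONVENTION = LabelConvention()


@dataclass(frozen=True)
class GeneLeaf:
    """A gene-tree leaf resolved under the label convention."""

    label: str
    species: str
    gene_id: str
    subfamily: str | None = None


@dataclass
class GeneTree:
    """An unrooted gene tree whose leaves are annotated genes.

    ``tree`` is the underlying dendropy tree (treated as unrooted; a basal
    bifurcation from rooted newick is collapsed on parse). Branch supports are
    normalised to [0, 1]; the original scale is recorded in ``support_scale``
    (``"fraction"`` or ``"percent"``).
    """

    tree: dendropy.Tree
    leaves: list[GeneLeaf]
    subfamily: str | None = None
    outgroup_labels: list[str] = field(default_factory=list)
    support_scale: str = "fraction"

    def __post_init__(self) -> None:
        labels = [lf.label for lf in self.leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeParseError(f"duplicate leaf labels in gene tree: {dupes}")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves]

    @property
    def species(self) -> set[str]:
        return {lf.species for lf in self.leaves}

    def leaf_by_label(self, label: str) -> GeneLeaf:
        for lf in self.leaves:
            if lf.label == label:
                return lf
        raise KeyError(label)

    @property
    def species_map(self) -> dict[str, str]:
        if not hasattr(self, "_species_map"):
            self._species_map = {lf.label: lf.species for lf in self.leaves}
        return self._species_map

    def species_of(self, label: str) -> str:
        return self.species_map[label]

    def as_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return s.strip()


def _normalise_supports(tree: dendropy.Tree) -> str:
    """Detect the support scale and normalise internal-node labels to [0,1]."""
    raw: list[tuple[dendropy.Node, float]] = []
    for nd in tree.preorder_internal_node_iter():
        if nd.label is None:
            continue
        try:
            val = float(nd.label)
        except ValueError:
            continue
        raw.append((nd, val))
    scale = "percent" if any(v > 1.0 for _, v in raw) else "fraction"
    for nd, val in raw:
        nd.label = repr(val / 100.0 if scale == "percent" else val)
    return scale


def parse_gene_tree(
    newick_text: str,
    convention: LabelConvention = DEFAULT_CONVENTION,
    subfamily: str | None = None,
) -> GeneTree:
    """Parse a newick gene tree, resolve leaves, prune the outgroup.

    Raises :class:`TreeParseError` on malformed newick or on trees with fewer
    than two non-outgroup leaves, and :class:`LabelConventionError` naming any
    leaf that violates the declared convention.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"malformed newick: {exc}") from exc

    all_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    outgroup_labels = sorted(l for l in all_labels if convention.is_outgroup(l))
    if outgroup_labels:
        tree.prune_taxa_with_labels(outgroup_labels)
        tree.purge_taxon_namespace()

    kept = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(kept) < 2:
        raise TreeParseError(
            f"gene tree must have at least 2 non-outgroup leaves, got {len(kept)}"
        )

    scale = _normalise_supports(tree)
    # unrooted convention: collapse a basal bifurcation left by rooted newick
    seed = tree.seed_node
    if len(seed.child_nodes()) == 2 and any(
        not c.is_leaf() for c in seed.child_nodes()
    ):
        tree.collapse_basal_bifurcation()
    tree.is_rooted = False

    leaves = []
    for label in kept:
        species, gene_id = convention.split(label)
        leaves.append(GeneLeaf(label=label, species=species, gene_id=gene_id, subfamily=subfamily))
    leaves.sort(key=lambda lf: lf.label)
    return GeneTree(
        tree=tree,
        leaves=leaves,
        subfamily=subfamily,
        outgroup_labels=outgroup_labels,
        support_scale=scale,
    )


def gene_tree_from_dendropy(
    tree: dendropy.Tree,
    convention: LabelConvention = DEFAULT_CONVENTION,
    subfamily: str | None = None,
) -> GeneTree:
    """Wrap an in-memory dendropy tree (e.g. a simulated one) as a GeneTree.

    Unlike :func:`parse_gene_tree` this admits single-leaf trees, which a
    birth-death simulation can legitimately produce.
    """
    leaves = []
    for lf in tree.leaf_node_iter():
        species, gene_id = convention.split(lf.taxon.label)
        leaves.append(
            GeneLeaf(label=lf.taxon.label, species=species, gene_id=gene_id, subfamily=subfamily)
        )
    leaves.sort(key=lambda l: l.label)
    tree.is_rooted = False
    return GeneTree(tree=tree, leaves=leaves, subfamily=subfamily)


def read_species_tree(source: str | Path, ultrametric_rtol: float | None = None) -> dendropy.Tree:
    """Read a rooted, dated species tree from newick text or a file path.

    If ``ultrametric_rtol`` is given, root-to-tip path lengths must agree
    within that relative tolerance (required for simulation).
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "(" in source:
        text = source
    else:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeParseError(f"malformed species tree newick: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeParseError("species tree tip labels are not unique")
    if ultrametric_rtol is not None:
        depths = []
        for lf in tree.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(d)
        dmax = max(depths)
        if dmax <= 0 or (dmax - min(depths)) / dmax > ultrametric_rtol:
            raise TreeParseError(
                f"species tree is not ultrametric within rtol={ultrametric_rtol}: "
                f"tip depths range {min(depths):g}..{dmax:g}"
            )
    return tree


def read_subfamily_registry(source: str | Path) -> dict[str, Path]:
    """Read the two-column (subfamily, gene-tree path) TSV registry.

    Returns a dict iterating in sorted (lexicographic) subfamily order.
    Relative paths are resolved against the registry file's directory.
    """
    path = Path(source)
    base = path.parent
    registry: dict[str, Path] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated columns, got {len(parts)}")
        subfam, tree_path = parts
        if subfam in registry:
            raise ValueError(f"{path}:{i}: duplicate subfamily {subfam!r}")
        p = Path(tree_path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"{path}:{i}: gene tree file not found: {p}")
        registry[subfam] = p
    return dict(sorted(registry.items()))


def write_orthogroup_clusters(sets: Sequence, path: str | Path) -> None:
    """Write orthogroup cluster lists: subfamily, orthogroup id, member labels.

    One line per orthogroup; ordering is (subfamily, smallest member label);
    members are comma-separated in sorted order. ``sets`` is a sequence of
    :class:`orthodiv.orthology.OrthogroupSet`.
    """
    rows: list[tuple[str, str, str]] = []
    for ogset in sets:
        subfam = ogset.subfamily or ""
        ogs = sorted(ogset.orthogroups, key=lambda og: min(og.members))
        for i, og in enumerate(ogs, start=1):
            rows.append((subfam, f"OG{i:04d}", ",".join(sorted(og.members))))
    rows.sort(key=lambda r: (r[0], r[2].split(",")[0]))
    out = "".join(f"{s}\t{g}\t{m}\n" for s, g, m in rows)
    Path(path).write_text(out)


def read_orthogroup_clusters(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read cluster lists written by :func:`write_orthogroup_clusters`."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{i}: expected 3 columns, got {len(parts)}")
        subfam, og_id, members = parts
        rows.append((subfam, og_id, members.split(",")))
    return rows
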