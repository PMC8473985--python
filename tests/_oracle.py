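"""Independent brute-force oracle for orthogroup extraction.

Works on a plain edge-graph of the tree (networkx), enumerating splits by
actual edge removal and testing in-paralog monophyly by rooted DFS from the
candidate's defining branch — no code shared with the library's
bipartition-based implementation beyond the newick parser.
"""

from __future__ import annotations

import itertools

import networkx as nx


def graph_from_gene_tree(gene_tree) -> tuple[nx.Graph, dict]:
    """Undirected graph of the dendropy tree; nodes are ids, leaves labelled."""
    g = nx.Graph()
    label = {}
    for nd in gene_tree.tree.preorder_node_iter():
        g.add_node(id(nd))
        if nd.taxon is not None:
            label[id(nd)] = nd.taxon.label
        for child in nd.child_nodes():
            g.add_edge(id(nd), id(child))
    return g, label


def oracle_splits(g: nx.Graph, label: dict) -> list[tuple[frozenset, frozenset]]:
    """All splits by removing each edge and reading off component leaf sets."""
    out = []
    seen = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp_u = nx.node_connected_component(h, u)
        side_u = frozenset(label[x] for x in comp_u if x in label)
        side_v = frozenset(label[x] for x in g.nodes if x in label) - side_u
        if not side_u or not side_v:
            continue
        key = frozenset((side_u, side_v))
        if key not in seen:
            seen.add(key)
            out.append((side_u, side_v))
    return out


def _rooted_clades(g: nx.Graph, label: dict, inside_node, outside_node) -> set[frozenset]:
    """Leaf sets of every subtree when the side containing ``inside_node`` is
    rooted at the (inside_node, outside_node) branch."""
    clades: set[frozenset] = set()

    def dfs(node, parent) -> frozenset:
        leaves = set()
        if node in label:
            leaves.add(label[node])
        for nb in g.neighbors(node):
            if nb != parent:
                leaves |= dfs(nb, node)
        fs = frozenset(leaves)
        clades.add(fs)
        return fs

    dfs(inside_node, outside_node)
    return clades


def oracle_valid(
    side: frozenset,
    clades: set[frozenset],
    species_of: dict,
    min_taxa: int,
    in_paralogs: bool,
) -> bool:
    by_species: dict[str, set] = {}
    for leaf in side:
        by_species.setdefault(species_of[leaf], set()).add(leaf)
    if len(by_species) < min_taxa:
        return False
    for group in by_species.values():
        if len(group) == 1:
            continue
        if not in_paralogs:
            return False
        if frozenset(group) not in clades:
            return False
    return True


def oracle_extract(gene_tree, min_taxa: int = 1, min_support: float = 0.0,
                   in_paralogs: bool = True) -> list[frozenset]:
    """Brute-force orthogroup partition with the same candidate pool and
    greedy ranking as the library contract, derived entirely from graph ops."""
    g, label = graph_from_gene_tree(gene_tree)
    species_of = {lf.label: lf.species for lf in gene_tree.leaves}
    all_leaves = frozenset(label.values())

    # support lookup from the library split enumeration is avoided: recompute
    # from node labels by pairing each edge with the deeper node's label
    support_of: dict[frozenset, float] = {}
    for nd in gene_tree.tree.preorder_node_iter():
        if nd is gene_tree.tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        key = frozenset((below, all_leaves - below))
        try:
            s = float(nd.label) if nd.label is not None else 1.0
        except (TypeError, ValueError):
            s = 1.0
        support_of[key] = s

    candidates: list[frozenset] = []
    edge_of_side: dict[frozenset, tuple] = {}
    for (u, v) in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        comp_u = nx.node_connected_component(h, u)
        side_u = frozenset(label[x] for x in comp_u if x in label)
        side_v = all_leaves - side_u
        if len(side_u) < 2 or len(side_v) < 2:
            continue  # pendant split: no nontrivial candidate
        key = frozenset((side_u, side_v))
        if support_of.get(key, 1.0) < min_support:
            continue
        for side, inside, outside in ((side_u, u, v), (side_v, v, u)):
            if side not in edge_of_side:
                edge_of_side[side] = (inside, outside)
                candidates.append(side)
    # the whole leaf set, validated against unrooted split sides
    whole_clades = set()
    for a, b in oracle_splits(g, label):
        whole_clades.add(a)
        whole_clades.add(b)
    whole_clades.add(all_leaves)

    valid = []
    for side in candidates:
        inside, outside = edge_of_side[side]
        clades = _rooted_clades(g, label, inside, outside)
        if oracle_valid(side, clades, species_of, min_taxa, in_paralogs):
            valid.append(side)
    if oracle_valid(all_leaves, whole_clades, species_of, min_taxa, in_paralogs):
        valid.append(all_leaves)

    def n_species(side):
        return len({species_of[l] for l in side})

    valid.sort(key=lambda s: (-n_species(s), -len(s), tuple(sorted(s))))
    accepted: list[frozenset] = []
    covered: set = set()
    for side in valid:
        if side & covered:
            continue
        accepted.append(side)
        covered |= side
    for leaf in sorted(all_leaves - covered):
        accepted.append(frozenset({leaf}))
    return accepted


def random_gene_tree_newick(rng, max_leaves: int = 12, max_species: int = 4,
                            with_supports: bool = True) -> str:
    """A random binary gene tree in newick, species drawn from a..d."""
    n = int(rng.integers(3, max_leaves + 1))
    n_sp = int(rng.integers(1, max_species + 1))
    species = [chr(ord("a") + i) for i in range(n_sp)]
    counters = {sp: 0 for sp in species}
    subtrees = []
    for _ in range(n):
        sp = species[int(rng.integers(0, n_sp))]
        counters[sp] += 1
        subtrees.append(f"{sp}_g{counters[sp]}:1.0")
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        supp = f"{int(rng.integers(50, 101))}" if with_supports else ""
        subtrees.append(f"({a},{b}){supp}:1.0")
    return "(" + ",".join(subtrees) + ");"
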