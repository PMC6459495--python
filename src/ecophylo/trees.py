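"""Species-level tree ensembles under phylogenetic uncertainty.

A genus-level ultrametric backbone is expanded to the species level by
grafting congeners as polytomies at the genus tips.  Phylogenetic
uncertainty within genera is then propagated by drawing an ensemble of fully
resolved trees: each polytomy is resolved independently per draw by
sequential random attachment — congeners are added one at a time to a
uniformly chosen branch inside the genus clade (its stem included), with the
attachment height uniform on that branch's height interval.  Tips stay at
the present, so every ensemble tree is ultrametric by construction.

Also provided: patristic distance matrices, the taxa-shuffle null
permutation of a distance matrix, and Newick I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import DistanceMatrix

__all__ = [
    "TreeEnsemble",
    "graft_species",
    "resolve_uncertainty",
    "patristic_distances",
    "taxa_shuffle",
    "read_newick",
    "write_newick",
    "tree_height",
    "is_binary",
    "ultrametricity_deviation",
]


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree with branch lengths from a Newick file."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy reports line/column in the message
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          real_value_format_specifier=".12g")


# ---------------------------------------------------------------------------
# Helpers


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            length = node.edge.length
            if length is None:
                raise ValueError(
                    f"missing branch length on edge above node "
                    f"{_node_name(node)!r}")
            depths[node] = depths[node.parent_node] + length
    return depths


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    leaves = [lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None]
    return "MRCA(" + ",".join(sorted(leaves)[:3]) + ")"


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    depths = _node_depths(tree)
    return max(d for n, d in depths.items() if n.is_leaf())


def _node_heights(tree: dendropy.Tree):
    """Heights above the present (deepest tip defines the present)."""
    depths = _node_depths(tree)
    height = max(d for n, d in depths.items() if n.is_leaf())
    return {n: height - d for n, d in depths.items()}, height


def is_binary(tree: dendropy.Tree) -> bool:
    return all(len(n.child_nodes()) == 2
               for n in tree.preorder_internal_node_iter())


def ultrametricity_deviation(tree: dendropy.Tree) -> float:
    """Relative spread of root-to-tip distances (0 for ultrametric trees)."""
    depths = _node_depths(tree)
    tip_depths = np.array([d for n, d in depths.items() if n.is_leaf()])
    rng = tip_depths.max() - tip_depths.min()
    return float(rng / tip_depths.max()) if tip_depths.max() > 0 else 0.0


def tip_labels(tree: dendropy.Tree) -> list:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Grafting


def _as_genus_lookup(genus_map) -> dict:
    """Normalize a species->genus mapping (dict or pandas Series)."""
    if isinstance(genus_map, pd.Series):
        items = genus_map.to_dict()
    elif isinstance(genus_map, Mapping):
        items = dict(genus_map)
    else:
        raise TypeError("genus_map must be a mapping or pandas Series")
    if not items:
        raise ValueError("empty genus map")
    return items


def graft_species(backbone: dendropy.Tree, genus_map) -> dendropy.Tree:
    """Replace each genus tip of the backbone by its species.

    A monotypic genus becomes a single species tip retaining the genus tip's
    depth; a genus with two or more species becomes a polytomy attached at
    the former genus tip, with zero-length branches so that all species tips
    sit at the present.  The genus stem branch keeps its backbone length.
    """
    lookup = _as_genus_lookup(genus_map)
    by_genus: dict = {}
    for sp, g in lookup.items():
        by_genus.setdefault(g, []).append(sp)
    backbone_tips = {lf.taxon.label for lf in backbone.leaf_node_iter()}
    missing = sorted(set(by_genus) - backbone_tips)
    if missing:
        raise ValueError(f"genera absent from backbone: {missing}")

    tree = backbone.clone(depth=1)
    tns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        genus = leaf.taxon.label
        species = sorted(by_genus.get(genus, []))
        if not species:
            continue
        if len(species) == 1:
            leaf.taxon = tns.require_taxon(label=species[0])
        else:
            leaf.taxon = None
            for sp in species:
                child = dendropy.Node(edge_length=0.0)
                child.taxon = tns.require_taxon(label=sp)
                leaf.add_child(child)
    return tree


# ---------------------------------------------------------------------------
# Polytomy resolution


def _subtree_edges(node, heights):
    """(child_node, lo, hi) height intervals for all edges inside a subtree."""
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        for c in n.child_nodes():
            out.append((c, heights[c], heights[n]))
            stack.append(c)
    return out


def _resolve_polytomy(node, heights, rng) -> None:
    """Resolve one polytomy in place by sequential uniform attachment."""
    parent = node.parent_node
    children = sorted(node.child_nodes(), key=_node_name)
    if parent is None:
        # Root polytomy: the root height is pinned, so keep the first two
        # children on the root and insert the rest below it.
        first, rest = children[:2], children[2:]
        anchor = node
        edges = []
        for c in first:
            edges.append((c, heights[c], heights[node]))
            edges.extend(_subtree_edges(c, heights))
    else:
        stem_top = heights[parent]
        for c in children:
            node.remove_child(c)
        parent.remove_child(node)
        first_child = children[0]
        parent.add_child(first_child)
        first_child.edge.length = stem_top - heights[first_child]
        rest = children[1:]
        edges = [(first_child, heights[first_child], stem_top)]
        edges.extend(_subtree_edges(first_child, heights))

    for c in rest:
        h_c = heights[c]
        valid = [e for e in edges if e[2] > h_c + 1e-12]
        if not valid:
            raise RuntimeError("no valid attachment branch for polytomy child")
        child_below, lo, hi = valid[rng.integers(len(valid))]
        t = rng.uniform(max(lo, h_c), hi)
        upper = child_below.parent_node
        upper.remove_child(child_below)
        w = dendropy.Node(edge_length=heights[upper] - t)
        upper.add_child(w)
        w.add_child(child_below)
        child_below.edge.length = t - heights[child_below]
        w.add_child(c)
        c.edge.length = t - h_c
        heights[w] = t
        edges.remove((child_below, lo, hi))
        edges.extend([(child_below, heights[child_below], t),
                      (w, t, heights[upper]),
                      (c, h_c, t)])
        edges.extend(_subtree_edges(c, heights))


@dataclass(frozen=True)
class TreeEnsemble:
    """Ordered collection of fully resolved trees on an identical tip set."""

    trees: tuple
    seed: int
    source: dendropy.Tree

    def __post_init__(self):
        if len(self.trees) < 1:
            raise ValueError("ensemble must contain at least one tree")
        tips0 = tip_labels(self.trees[0])
        for t in self.trees[1:]:
            if tip_labels(t) != tips0:
                raise ValueError("ensemble trees differ in tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> list:
        return tip_labels(self.trees[0])


def resolve_uncertainty(tree: dendropy.Tree, n_trees: int, seed: int) -> TreeEnsemble:
    """Draw an ensemble of random resolutions of every polytomy.

    Each tree in the ensemble resolves every polytomy independently.  A
    fully resolved input yields ``n_trees`` identical copies.
    """
    if int(n_trees) < 1:
        raise ValueError("n_trees must be >= 1")
    n_trees = int(n_trees)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        work = tree.clone(depth=1)
        polytomies = [n for n in work.preorder_internal_node_iter()
                      if len(n.child_nodes()) > 2]
        if polytomies:
            heights, _ = _node_heights(work)
            for node in polytomies:
                _resolve_polytomy(node, heights, rng)
        out.append(work)
    return TreeEnsemble(trees=tuple(out), seed=int(seed), source=tree)


# ---------------------------------------------------------------------------
# Patristic distances and the taxa shuffle


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise sums of branch lengths along tip-to-tip paths."""
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    # postorder merge: each node carries (tip_index, distance-to-node) pairs
    carry: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            carry[node] = [(index[node.taxon.label], 0.0)]
            continue
        groups = []
        for c in node.child_nodes():
            length = c.edge.length
            if length is None:
                raise ValueError(
                    f"missing branch length on edge above {_node_name(c)!r}")
            groups.append([(i, d + length) for i, d in carry.pop(c)])
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i, di in groups[a]:
                    for j, dj in groups[b]:
                        D[i, j] = D[j, i] = di + dj
        carry[node] = [p for g in groups for p in g]
    return DistanceMatrix(labels, D)


def taxa_shuffle(dist: DistanceMatrix, seed=None) -> DistanceMatrix:
    """Permute species identities on a distance matrix (null model).

    Rows and columns are jointly permuted by one uniform random permutation,
    leaving the multiset of off-diagonal distances unchanged while breaking
    the link between species identity and phylogenetic position.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dist))
    return DistanceMatrix(dist.labels, dist.values[np.ix_(perm, perm)])
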