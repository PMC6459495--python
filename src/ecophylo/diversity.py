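"""Per-unit alpha diversity: richness, Gini-Simpson, Faith PD, Rao entropy.

Phylogenetic metrics accept either a single tree or a tree ensemble; with an
ensemble the arithmetic mean and SD across trees are reported, propagating
within-genus phylogenetic uncertainty into the diversity estimates.

Conventions
-----------
* "Simpson index" means the Gini-Simpson form 1 - sum(p_i^2); with this
  convention Rao's quadratic entropy on a constant distance matrix reduces
  to c times the Simpson index.
* Faith PD is root-inclusive by default (a single-species community has
  PD equal to its root-to-tip distance); pass ``include_root=False`` for the
  crown-only variant.
* Occurrence proportions (counts divided by the unit total), not raw
  abundances, weight both the Simpson index and Rao entropy.
* Rao uses patristic distances rescaled to [0, 1] by the matrix maximum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, validate_community_matrix
from .trees import TreeEnsemble, patristic_distances

__all__ = [
    "species_richness",
    "simpson_diversity",
    "faith_pd",
    "rao_quadratic",
    "ensemble_diversity",
    "diversity_table",
]


def species_richness(W: pd.DataFrame) -> pd.Series:
    """Number of species with a positive count in each unit."""
    validate_community_matrix(W)
    return (W > 0).sum(axis=1).rename("S")


def simpson_diversity(W: pd.DataFrame) -> pd.Series:
    """Gini-Simpson diversity 1 - sum(p_i^2); NaN for all-zero units."""
    validate_community_matrix(W)
    vals = W.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = vals / totals[:, None]
        D = 1.0 - np.nansum(p ** 2, axis=1)
    D = np.where(totals > 0, D, np.nan)
    return pd.Series(D, index=W.index, name="D")


def _present_species(tree) -> dict:
    return {lf.taxon.label: lf for lf in tree.leaf_node_iter()}


def faith_pd(tree, W: pd.DataFrame, include_root: bool = True) -> pd.Series:
    """Faith's phylogenetic diversity per unit.

    Total branch length of the minimal subtree spanning the unit's species,
    including the path to the root by default.
    """
    validate_community_matrix(W)
    leaves = _present_species(tree)
    missing = sorted(set(W.columns) - set(leaves))
    if missing:
        raise ValueError(f"species absent from tree: {missing}")

    # per-unit boolean presence of each node's subtree, computed bottom-up
    nodes = list(tree.postorder_node_iter())
    node_idx = {id(n): i for i, n in enumerate(nodes)}
    n_units = len(W.index)
    present = np.zeros((len(nodes), n_units), dtype=bool)
    Wb = (W.to_numpy() > 0)
    col = {sp: j for j, sp in enumerate(W.columns)}
    lengths = np.zeros(len(nodes))
    for i, node in enumerate(nodes):
        if node.is_leaf():
            lab = node.taxon.label
            if lab in col:
                present[i] = Wb[:, col[lab]]
        else:
            for c in node.child_nodes():
                present[i] |= present[node_idx[id(c)]]
        if node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError("missing branch length in tree")
            lengths[i] = node.edge.length

    if include_root:
        pd_vals = lengths @ present
    else:
        # crown-only: drop edges on the naked path above the unit's MRCA
        pd_vals = np.zeros(n_units)
        for u in range(n_units):
            mask = present[:, u]
            if not mask.any():
                continue
            total = lengths[mask].sum()
            # walk down from the root while a single child subtree is occupied
            node = tree.seed_node
            while True:
                occupied = [c for c in node.child_nodes()
                            if present[node_idx[id(c)], u]]
                if len(occupied) != 1:
                    break
                total -= lengths[node_idx[id(occupied[0])]]
                node = occupied[0]
            pd_vals[u] = total
    return pd.Series(pd_vals, index=W.index, name="PD")


def rao_quadratic(dist: DistanceMatrix, W: pd.DataFrame,
                  rescale: bool = True) -> pd.Series:
    """Rao's quadratic entropy sum_ij d_ij p_i p_j per unit.

    ``dist`` is rescaled to unit maximum by default so the metric is
    commensurable across trees of different depths.
    """
    validate_community_matrix(W)
    missing = sorted(set(W.columns) - set(dist.labels))
    if missing:
        raise ValueError(f"species absent from distance matrix: {missing}")
    d = dist.rescaled() if rescale else dist
    d = d.reorder(list(W.columns))
    vals = W.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals[:, None] > 0, vals / totals[:, None], 0.0)
    pr = np.einsum("ui,ij,uj->u", p, d.values, p)
    pr = np.where(totals > 0, pr, np.nan)
    return pd.Series(pr, index=W.index, name="PR")


def ensemble_diversity(metric: str, ensemble: TreeEnsemble, W: pd.DataFrame,
                       include_root: bool = True,
                       rescale: bool = True) -> pd.DataFrame:
    """Mean and SD of a tree-dependent metric ('PD' or 'PR') across trees."""
    if metric not in ("PD", "PR"):
        raise ValueError("metric must be 'PD' or 'PR'")
    per_tree = []
    for tree in ensemble:
        if metric == "PD":
            per_tree.append(faith_pd(tree, W, include_root=include_root))
        else:
            per_tree.append(rao_quadratic(patristic_distances(tree), W,
                                          rescale=rescale))
    stacked = pd.concat(per_tree, axis=1)
    sd = stacked.std(axis=1, ddof=0)
    sd[stacked.nunique(axis=1) <= 1] = 0.0  # identical trees: exactly zero
    return pd.DataFrame({
        f"{metric}_mean": stacked.mean(axis=1),
        f"{metric}_sd": sd,
    })


def diversity_table(W: pd.DataFrame, ensemble: TreeEnsemble,
                    include_root: bool = True) -> pd.DataFrame:
    """S, D and ensemble-averaged PD/PR (with SDs) for every unit."""
    parts = [species_richness(W), simpson_diversity(W),
             ensemble_diversity("PD", ensemble, W, include_root=include_root),
             ensemble_diversity("PR", ensemble, W)]
    return pd.concat(parts, axis=1)
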