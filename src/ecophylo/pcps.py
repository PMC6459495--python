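"""Fuzzy-weighted phylobetadiversity (PCPS) with taxa-shuffle null models.

The phylogeny-weighted composition matrix is built in three steps from a
community matrix W (units x species) and a patristic distance matrix D
rescaled to [0, 1]:

* S = 1 - D - pairwise phylogenetic similarities;
* Q - fuzzy weights: each column of S divided by its column total, so every
  column of Q sums to one;
* P = W Q^T - each species' occurrence total is redistributed over its
  phylogenetic neighbourhood; row totals of W are conserved exactly.

Principal Coordinates of Phylogenetic Structure (PCPS) are the PCoA axes of
a square-root Bray-Curtis dissimilarity among the rows of P.  Association
between P and an external factor is tested with a PERMANOVA pseudo-F whose
null distribution comes from taxa-shuffle permutations: the distance matrix
is relabelled at random, S/Q/P are rebuilt, and the statistic recomputed,
while the community matrix is kept fixed.  Run across a tree ensemble, the
per-tree p-values summarise whether the factor association is structured by
phylogeny robustly to within-genus uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, validate_community_matrix
from .ordination import OrdinationResult, PermanovaResult, pcoa, _group_info, pseudo_f
from .trees import TreeEnsemble, patristic_distances
from ._rng import substream_seed

__all__ = [
    "phylo_similarity",
    "fuzzy_weights",
    "p_matrix",
    "pcps_ordination",
    "pcps_factor_test",
    "pcps_ensemble_test",
    "PcpsEnsembleReport",
]


def phylo_similarity(dist: DistanceMatrix, rescale: bool = True) -> pd.DataFrame:
    """Similarity matrix S = 1 - D with D rescaled to unit maximum."""
    if dist.max == 0:
        raise ValueError("all species are phylogenetically identical "
                         "(zero distance matrix)")
    d = dist.rescaled() if rescale else dist
    if d.values.max() > 1 + 1e-12:
        raise ValueError("distances must lie in [0, 1]; pass rescale=True")
    S = 1.0 - d.values
    return pd.DataFrame(S, index=list(d.labels), columns=list(d.labels))


def fuzzy_weights(S: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize S: every column of Q sums to one."""
    vals = np.asarray(S, dtype=float)
    totals = vals.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero column total in similarity matrix")
    Q = vals / totals[None, :]
    return pd.DataFrame(Q, index=S.index, columns=S.columns)


def p_matrix(W: pd.DataFrame, Q: pd.DataFrame) -> pd.DataFrame:
    """Phylogeny-weighted composition P = W Q^T (row totals conserved)."""
    validate_community_matrix(W)
    if sorted(W.columns) != sorted(Q.columns):
        raise ValueError("species labels of W and Q do not match")
    Qa = Q.loc[list(W.columns), list(W.columns)].to_numpy()
    P = W.to_numpy(dtype=float) @ Qa.T
    return pd.DataFrame(P, index=W.index, columns=W.columns)


def pcps_ordination(P: pd.DataFrame, sqrt_transform: bool = True) -> OrdinationResult:
    """PCPS axes: PCoA of (square-root) Bray-Curtis dissimilarity of P."""
    from .ordination import bray_curtis

    return pcoa(bray_curtis(P, sqrt_transform=sqrt_transform))


# ---------------------------------------------------------------------------
# Taxa-shuffle tests (array fast path)


def _pcps_f(Wv: np.ndarray, Dv: np.ndarray, codes: np.ndarray, g: int,
            sizes: np.ndarray, sqrt_transform: bool = True) -> float:
    """Pseudo-F of the factor on the dissimilarity of P, from raw arrays."""
    totals = Dv.max()
    S = 1.0 - Dv / totals
    Q = S / S.sum(axis=0)[None, :]
    P = Wv @ Q.T
    d = pdist(P, metric="braycurtis")
    if sqrt_transform:
        d = np.sqrt(d)
    D2 = squareform(d) ** 2
    return pseudo_f(D2, codes, g, sizes)


def pcps_factor_test(W: pd.DataFrame, dist: DistanceMatrix, factor,
                     n_perm: int = 9999, seed: Optional[int] = None,
                     sqrt_transform: bool = True) -> PermanovaResult:
    """Taxa-shuffle test of a factor on phylogeny-weighted composition.

    The observed statistic is the PERMANOVA pseudo-F of the factor on the
    dissimilarity of P.  Null draws relabel the species on the distance
    matrix, rebuild S, Q and P (the community matrix is untouched), and
    recompute the statistic; the p-value uses the +1 rule.  A significant
    result means the factor association is structured by the phylogenetic
    relationships among species, not merely by species composition.
    """
    validate_community_matrix(W)
    codes, g, sizes = _group_info(factor)
    if len(codes) != len(W.index):
        raise ValueError("factor length does not match community matrix")
    d = dist.reorder(list(W.columns))
    Wv = W.to_numpy(dtype=float)
    Dv = d.values
    if Dv.max() == 0:
        raise ValueError("zero distance matrix")
    n_perm = int(n_perm)
    f_obs = _pcps_f(Wv, Dv, codes, g, sizes, sqrt_transform)
    rng = np.random.default_rng(seed)
    count = 0
    n_sp = Dv.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n_sp)
        f_b = _pcps_f(Wv, Dv[np.ix_(perm, perm)], codes, g, sizes,
                      sqrt_transform)
        if f_b >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(statistic=float(f_obs), p_value=float(p),
                           n_permutations=n_perm, seed=seed, r2=np.nan,
                           method="taxa_shuffle")


@dataclass(frozen=True)
class PcpsEnsembleReport:
    """Per-tree taxa-shuffle p-values across a tree ensemble."""

    p_values: np.ndarray
    alpha: float
    n_permutations: int
    seed: Optional[int]
    axis1_eigenvalue_mean: float
    axis1_proportion_mean: float
    decision: str = field(default="")

    @property
    def n_trees(self) -> int:
        return len(self.p_values)

    @property
    def proportion_significant(self) -> float:
        return float((self.p_values <= self.alpha).mean())


def pcps_ensemble_test(W: pd.DataFrame, ensemble: TreeEnsemble, factor,
                       alpha: float = 0.05, n_perm: int = 9999,
                       seed: Optional[int] = None,
                       sqrt_transform: bool = True) -> PcpsEnsembleReport:
    """Run the taxa-shuffle factor test on every tree of an ensemble.

    Reports per-tree p-values and the proportion with p <= alpha.  Each
    tree's null permutations use a substream seed derived from ``seed`` and
    the tree index, so identical trees yield identical p-values and results
    do not depend on evaluation order.
    """
    p_values = np.empty(len(ensemble))
    eig1, prop1 = np.empty(len(ensemble)), np.empty(len(ensemble))
    # one shared null-permutation substream per ensemble: identical trees
    # must yield identical p-values
    sub = substream_seed(seed if seed is not None else 0, "pcps_shuffle")
    for i, tree in enumerate(ensemble):
        dist = patristic_distances(tree)
        res = pcps_factor_test(W, dist, factor, n_perm=n_perm, seed=sub,
                               sqrt_transform=sqrt_transform)
        p_values[i] = res.p_value
        S = phylo_similarity(dist.reorder(list(W.columns)))
        ord_res = pcps_ordination(p_matrix(W, fuzzy_weights(S)),
                                  sqrt_transform=sqrt_transform)
        eig1[i] = ord_res.eigenvalues[0]
        prop1[i] = ord_res.proportion_explained[0]
    prop_sig = float((p_values <= alpha).mean())
    if prop_sig == 0.0:
        decision = (f"p(taxa shuffle) > {alpha} for all {len(ensemble)} "
                    "phylogenetic trees: no evidence that the factor "
                    "association is phylogenetically structured")
    else:
        decision = (f"{int((p_values <= alpha).sum())} of {len(ensemble)} "
                    f"trees returned p <= {alpha}")
    return PcpsEnsembleReport(p_values=p_values, alpha=alpha,
                              n_permutations=int(n_perm), seed=seed,
                              axis1_eigenvalue_mean=float(eig1.mean()),
                              axis1_proportion_mean=float(prop1.mean()),
                              decision=decision)
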