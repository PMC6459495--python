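"""Bray-Curtis dissimilarity, principal coordinates, and PERMANOVA.

PCoA uses Gower double-centering of the squared distances; axes with
eigenvalues below 1e-10 (including all negative ones) are dropped and the
proportion of variation uses the positive-eigenvalue sum as denominator.
No Lingoes/Cailliez correction is applied.

PERMANOVA follows the classical one-way decomposition of squared
inter-point distances: pseudo-F = (SS_among/(g-1)) / (SS_within/(n-g)),
with the p-value from free permutation of unit labels and the +1 rule
(the observed statistic counts in both numerator and denominator), or from
exhaustive enumeration of distinct group assignments when requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations
from math import factorial
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, validate_community_matrix

__all__ = ["bray_curtis", "pcoa", "permanova", "OrdinationResult",
           "PermanovaResult"]


def bray_curtis(W: pd.DataFrame, sqrt_transform: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between unit rows.

    ``sqrt_transform=True`` returns the square root of each dissimilarity,
    which embeds (near-)metrically and avoids negative PCoA eigenvalues.
    """
    if isinstance(W, pd.DataFrame):
        vals = W.to_numpy(dtype=float)
        labels = list(W.index)
    else:
        vals = np.asarray(W, dtype=float)
        labels = [f"u{i}" for i in range(vals.shape[0])]
    if np.any(vals < 0):
        raise ValueError("negative entries in community matrix")
    zero = vals.sum(axis=1) == 0
    if zero.any():
        bad = [labels[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sampling units: {bad}")
    d = pdist(vals, metric="braycurtis")
    if sqrt_transform:
        d = np.sqrt(d)
    return DistanceMatrix(labels, squareform(d))


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinates embedding."""

    eigenvalues: np.ndarray          # retained, descending
    scores: pd.DataFrame             # units x retained axes
    proportion_explained: np.ndarray
    all_eigenvalues: np.ndarray      # full spectrum, descending

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def pcoa(dist: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Principal Coordinates Analysis of a distance matrix."""
    n = len(dist)
    if n < 3:
        raise ValueError("PCoA needs at least 3 units")
    D2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_tol
    pos_sum = evals[evals > 0].sum()
    kept = evals[keep]
    scores = evecs[:, keep] * np.sqrt(kept)
    cols = [f"Axis{i + 1}" for i in range(keep.sum())]
    return OrdinationResult(
        eigenvalues=kept,
        scores=pd.DataFrame(scores, index=list(dist.labels), columns=cols),
        proportion_explained=(kept / pos_sum if pos_sum > 0
                              else np.zeros_like(kept)),
        all_eigenvalues=evals,
    )


@dataclass(frozen=True)
class PermanovaResult:
    statistic: float          # pseudo-F
    p_value: float
    n_permutations: int
    seed: Optional[int]
    r2: float
    degenerate: bool = False
    method: str = "free"


def _group_info(grouping) -> tuple:
    grouping = np.asarray(grouping)
    levels, codes = np.unique(grouping, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 units: {small}")
    return codes, len(levels), sizes


def _pseudo_f_terms(D2: np.ndarray, codes: np.ndarray, g: int,
                    sizes: np.ndarray):
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    onehot = np.eye(g)[codes]                      # n x g
    within_pergroup = np.einsum("ig,ij,jg->g", onehot, D2, onehot) / 2.0
    ss_within = (within_pergroup / sizes).sum()
    ss_among = ss_total - ss_within
    return ss_total, ss_within, ss_among


def pseudo_f(D2: np.ndarray, codes: np.ndarray, g: int, sizes: np.ndarray) -> float:
    n = D2.shape[0]
    ss_total, ss_within, ss_among = _pseudo_f_terms(D2, codes, g, sizes)
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def _batched_f(D2: np.ndarray, codes_batch: np.ndarray, g: int,
               sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for a (B, n) batch of label assignments."""
    B, n = codes_batch.shape
    onehot = np.zeros((B, n, g))
    rows = np.arange(n)
    for b in range(B):  # cheap relative to the einsum below
        onehot[b, rows, codes_batch[b]] = 1.0
    within = np.einsum("big,ij,bjg->bg", onehot, D2, onehot) / 2.0
    ss_total = D2.sum() / (2.0 * n)
    ss_within = (within / sizes).sum(axis=1)
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova(dist: DistanceMatrix, grouping, n_perm: int = 9999,
              seed: Optional[int] = None, method: str = "free") -> PermanovaResult:
    """One-way permutational multivariate analysis of variance.

    Parameters
    ----------
    grouping : sequence aligned with ``dist.labels``
    method : "free" for random label permutations (+1 rule) or "exact" for
        enumeration of all distinct assignments of labels to groups.
    """
    codes, g, sizes = _group_info(grouping)
    n = len(dist)
    if len(codes) != n:
        raise ValueError("grouping length does not match distance matrix")
    D2 = dist.values ** 2
    if D2.sum() == 0:
        return PermanovaResult(statistic=np.nan, p_value=np.nan,
                               n_permutations=0, seed=seed, r2=np.nan,
                               degenerate=True, method=method)
    ss_total, ss_within, ss_among = _pseudo_f_terms(D2, codes, g, sizes)
    f_obs = (ss_among / (g - 1)) / (ss_within / (n - g))
    r2 = ss_among / ss_total

    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration only supported for n <= 9")
        seen = set()
        f_null = []
        for perm in _iter_permutations(range(n)):
            key = tuple(codes[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            f_null.append(pseudo_f(D2, np.array(key), g, sizes))
        f_null = np.array(f_null)
        p = float((f_null >= f_obs - 1e-12).mean())
        return PermanovaResult(statistic=float(f_obs), p_value=p,
                               n_permutations=len(f_null), seed=seed, r2=float(r2),
                               method="exact")

    if method != "free":
        raise ValueError(f"unknown method {method!r}")
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 256
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        f_b = _batched_f(D2, codes[perms], g, sizes)
        count += int((f_b >= f_obs - 1e-12).sum())
        done += b
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(statistic=float(f_obs), p_value=float(p),
                           n_permutations=n_perm, seed=seed, r2=float(r2))
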