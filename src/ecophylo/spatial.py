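"""Collinearity screening, spatial eigenvectors, RDA and variation partitioning.

* ``vif_screen`` iteratively removes the predictor with the largest variance
  inflation factor until all VIFs fall at or below the threshold (default 3).
* ``pcnm`` builds Principal Coordinates of Neighbour Matrices: inter-site
  distances (km, equirectangular projection of lon/lat by default) are
  truncated at the longest minimum-spanning-tree edge, far pairs replaced by
  four times the threshold, and the positive-eigenvalue PCoA eigenvectors
  returned as spatial predictors.
* ``rda`` is a least-squares redundancy analysis with permutation tests;
  ``forward_select`` adds predictors greedily, testing the best remaining
  candidate's partial F against permutations of the max-F statistic so the
  per-step family-wise inclusion error stays at alpha under the null.
* ``varpart`` decomposes the adjusted R2 of a response matrix into pure
  environmental [a], spatially structured environmental [b], pure spatial
  [c], and residual [d] fractions, with permutation tests for the testable
  fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .containers import validate_community_matrix

__all__ = [
    "remove_singletons",
    "vif_screen",
    "pcnm",
    "PcnmBasis",
    "hellinger",
    "rda",
    "RdaResult",
    "forward_select",
    "ForwardSelectionResult",
    "varpart",
    "VarpartResult",
]


def remove_singletons(W: pd.DataFrame) -> pd.DataFrame:
    """Drop species whose total occurrence count over all units equals 1."""
    validate_community_matrix(W)
    totals = W.sum(axis=0)
    keep = W.columns[totals != 1]
    if len(keep) == 0:
        raise ValueError("all species are singletons")
    return W[keep]


def hellinger(W: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of within-unit proportions."""
    vals = W.to_numpy(dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("all-zero rows cannot be Hellinger-transformed")
    return pd.DataFrame(np.sqrt(vals / totals), index=W.index,
                        columns=W.columns)


# ---------------------------------------------------------------------------
# VIF screening


def _vif_values(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(env: pd.DataFrame, threshold: float = 3.0):
    """Iteratively drop the highest-VIF variable until all VIF <= threshold.

    Returns ``(retained, table)`` where ``table`` records each round's VIFs
    and which variable was removed.  Among equal (e.g. both infinite) VIFs,
    the later-listed variable is removed first.
    """
    if env.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 variables")
    if env.shape[0] <= env.shape[1] + 1:
        raise ValueError("need n > p + 1 observations for VIF screening")
    cols = list(env.columns)
    rounds = []
    while True:
        X = env[cols].to_numpy(dtype=float)
        vifs = _vif_values(X)
        row = dict(zip(cols, vifs))
        worst = np.max(vifs)
        if worst <= threshold:
            rounds.append({"removed": None, **row})
            break
        # later-listed first among ties (incl. perfectly collinear pairs)
        candidates = [i for i, v in enumerate(vifs)
                      if (np.isinf(v) and np.isinf(worst)) or v == worst]
        drop_idx = candidates[-1]
        if np.isinf(worst):
            warnings.warn(
                f"perfect collinearity: removing {cols[drop_idx]!r}",
                stacklevel=2)
        rounds.append({"removed": cols[drop_idx], **row})
        cols.pop(drop_idx)
        if len(cols) < 2:
            break
    table = pd.DataFrame(rounds)
    return cols, table


# ---------------------------------------------------------------------------
# PCNM


@dataclass(frozen=True)
class PcnmBasis:
    """Positive-eigenvalue spatial eigenvectors from a truncated distance."""

    vectors: pd.DataFrame     # sites x PCNM axes, unit-normalized columns
    eigenvalues: np.ndarray
    truncation: float

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


def pcnm(coords: pd.DataFrame, projected: bool = True,
         eig_rtol: float = 1e-8) -> PcnmBasis:
    """Principal Coordinates of Neighbour Matrices from site coordinates.

    ``coords`` has columns ``lon``/``lat`` (decimal degrees; converted to km
    by an equirectangular projection when ``projected``) or arbitrary
    ``x``/``y`` columns used as-is when ``projected=False``.
    """
    if len(coords) < 3:
        raise ValueError("PCNM needs at least 3 sites")
    if projected and {"lon", "lat"} <= set(coords.columns):
        from .synthetic import km_distances
        D = km_distances(coords)
    else:
        pts = coords.to_numpy(dtype=float)
        diff = pts[:, None, :] - pts[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    if np.any(off == 0):
        raise ValueError("duplicate site coordinates")
    mst = minimum_spanning_tree(D).toarray()
    threshold = float(mst.max())
    trunc = D.copy()
    trunc[trunc > threshold] = 4.0 * threshold
    np.fill_diagonal(trunc, 0.0)

    D2 = trunc ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_rtol * max(evals.max(), 1.0)
    vecs = evecs[:, keep]
    cols = [f"PCNM{i + 1}" for i in range(keep.sum())]
    return PcnmBasis(
        vectors=pd.DataFrame(vecs, index=coords.index, columns=cols),
        eigenvalues=evals[keep],
        truncation=threshold,
    )


# ---------------------------------------------------------------------------
# RDA


def _as_matrix(A) -> np.ndarray:
    vals = A.to_numpy(dtype=float) if isinstance(A, pd.DataFrame) else np.asarray(A, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    return vals


def _center(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0, keepdims=True)


def _drop_dependent_columns(X: np.ndarray, names) -> tuple:
    keep: list = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-10) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping rank-deficient predictors: {dropped}",
                      stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def _fit_ss(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Sum of squares of fitted values from least squares (no intercept:
    both sides centered)."""
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fit = Xc @ beta
    return float((fit ** 2).sum())


@dataclass(frozen=True)
class RdaResult:
    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: Optional[float]
    n_permutations: int
    seed: Optional[int]
    rank: int
    predictors: tuple


def adjusted_r2(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda(Y, X, n_perm: int = 999, seed: Optional[int] = None) -> RdaResult:
    """Redundancy analysis of response matrix Y on predictors X.

    Y is column-centered; R2 = SS_fit / SS_total; the permutation test
    permutes rows of Y (+1 rule).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(_as_matrix(X).shape[1])]
    Yc = _center(_as_matrix(Y))
    Xc = _center(_as_matrix(X))
    n = Yc.shape[0]
    Xc, names = _drop_dependent_columns(Xc, names)
    m = Xc.shape[1]
    if n <= m + 1:
        raise ValueError("need n > rank(X) + 1 observations")
    ss_total = float((Yc ** 2).sum())
    if ss_total == 0:
        raise ValueError("response matrix has zero variance")
    ss_fit = _fit_ss(Yc, Xc)
    r2 = ss_fit / ss_total
    f_obs = (ss_fit / m) / ((ss_total - ss_fit) / (n - m - 1))
    p = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            Yp = Yc[rng.permutation(n)]
            ss_p = _fit_ss(Yp, Xc)
            f_p = (ss_p / m) / ((ss_total - ss_p) / (n - m - 1))
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (int(n_perm) + 1)
    return RdaResult(r2=r2, adj_r2=adjusted_r2(r2, n, m), pseudo_f=f_obs,
                     p_value=p, n_permutations=int(n_perm or 0), seed=seed,
                     rank=m, predictors=tuple(names))


# ---------------------------------------------------------------------------
# Forward selection


@dataclass(frozen=True)
class ForwardSelectionResult:
    selected: tuple                 # in order of entry
    table: pd.DataFrame             # per-step statistics
    alpha: float
    n_permutations: int
    seed: Optional[int]


def _partial_f(Yc, X_sel, x_cand) -> tuple:
    """Partial F of one candidate given already-selected predictors."""
    n = Yc.shape[0]
    m_sel = X_sel.shape[1] if X_sel is not None else 0
    ss_total = float((Yc ** 2).sum())
    ss_sel = _fit_ss(Yc, X_sel) if m_sel else 0.0
    X_full = x_cand if X_sel is None else np.hstack([X_sel, x_cand])
    ss_full = _fit_ss(Yc, X_full)
    df_res = n - m_sel - 1 - 1
    if df_res <= 0:
        return np.nan, ss_full
    f = (ss_full - ss_sel) / ((ss_total - ss_full) / df_res)
    return f, ss_full


def forward_select(Y, X, alpha: float = 0.05, n_perm: int = 999,
                   seed: Optional[int] = None) -> ForwardSelectionResult:
    """Greedy forward selection of RDA predictors.

    At each step the candidate with the highest partial F enters, provided
    its permutation p-value (computed for the *maximum* partial F over the
    remaining candidates, which keeps the per-step family-wise inclusion
    error at alpha under the null) is <= alpha.  Ties are broken by larger
    adjusted R2 of the extended model, then input order.  ``alpha=1``
    selects all variables in descending-F order.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(_as_matrix(X).shape[1])]
    Yc = _center(_as_matrix(Y))
    Xc = _center(_as_matrix(X))
    n = Yc.shape[0]
    rng = np.random.default_rng(seed)
    remaining = list(range(Xc.shape[1]))
    selected: list = []
    rows = []
    ss_total = float((Yc ** 2).sum())
    while remaining:
        X_sel = Xc[:, selected] if selected else None
        if X_sel is not None and n - X_sel.shape[1] - 2 <= 0:
            break
        stats = []
        for j in remaining:
            f_j, ss_full_j = _partial_f(Yc, X_sel, Xc[:, [j]])
            m_full = (0 if X_sel is None else X_sel.shape[1]) + 1
            adj = adjusted_r2(ss_full_j / ss_total, n, m_full)
            stats.append((f_j, adj, j))
        # best candidate: highest F, ties by adjusted R2 then input order
        best_f = np.nanmax([s[0] for s in stats])
        tied = [s for s in stats if np.isclose(s[0], best_f, rtol=1e-12, atol=1e-12)]
        tied.sort(key=lambda s: (-s[1], s[2]))
        _, best_adj, best_j = tied[0]

        if alpha >= 1.0:
            p = 0.0
        else:
            count = 0
            for _ in range(int(n_perm)):
                # permute the response residuals under the current model
                if X_sel is None:
                    Yp = Yc[rng.permutation(n)]
                else:
                    beta, *_ = np.linalg.lstsq(X_sel, Yc, rcond=None)
                    fit = X_sel @ beta
                    Yp = fit + (Yc - fit)[rng.permutation(n)]
                f_max = -np.inf
                for j in remaining:
                    f_j, _ = _partial_f(Yp, X_sel, Xc[:, [j]])
                    if f_j > f_max:
                        f_max = f_j
                if f_max >= best_f - 1e-12:
                    count += 1
            p = (count + 1) / (int(n_perm) + 1)
        rows.append({"variable": names[best_j], "partial_F": best_f,
                     "adj_r2": best_adj, "p_value": p,
                     "entered": p <= alpha})
        if p > alpha:
            break
        selected.append(best_j)
        remaining.remove(best_j)
    return ForwardSelectionResult(
        selected=tuple(names[j] for j in selected),
        table=pd.DataFrame(rows),
        alpha=alpha, n_permutations=int(n_perm), seed=seed)


# ---------------------------------------------------------------------------
# Variation partitioning


@dataclass(frozen=True)
class VarpartResult:
    """Adjusted-R2 fractions [a]-[d] and tests for the testable components.

    ``fractions`` uses adjusted R2 (the reporting convention for variation
    partitioning); ``raw_fractions`` holds the unadjusted decomposition, for
    which exact identities such as [b] = 0 under orthogonal predictor sets
    hold to machine precision.
    """

    fractions: dict           # adjusted R2 for a, b, c, d, ab, bc, abc
    raw_fractions: dict       # same keys, unadjusted R2
    tests: dict               # {name: {"F":, "p":, "df":}} for a, c, ab, bc, abc
    n_permutations: int
    seed: Optional[int]

    def __post_init__(self):
        s = (self.fractions["a"] + self.fractions["b"]
             + self.fractions["c"] + self.fractions["d"])
        if abs(s - 1.0) > 1e-10:
            raise ValueError("fractions do not sum to 1")


def _partial_rda_test(Yc, X, Z, n_perm, rng) -> dict:
    """Permutation test of X's contribution conditional on Z."""
    n = Yc.shape[0]
    m_x, m_z = X.shape[1], Z.shape[1]
    ss_total = float((Yc ** 2).sum())
    beta_z, *_ = np.linalg.lstsq(Z, Yc, rcond=None)
    fit_z = Z @ beta_z
    XZ = np.hstack([Z, X])
    ss_z = _fit_ss(Yc, Z)
    ss_full = _fit_ss(Yc, XZ)
    df_res = n - m_x - m_z - 1
    f_obs = ((ss_full - ss_z) / m_x) / ((ss_total - ss_full) / df_res)
    count = 0
    resid = Yc - fit_z
    for _ in range(int(n_perm)):
        Yp = fit_z + resid[rng.permutation(n)]
        ss_p_full = _fit_ss(Yp, XZ)
        ss_p_z = _fit_ss(Yp, Z)
        ss_p_tot = float((Yp ** 2).sum())
        f_p = ((ss_p_full - ss_p_z) / m_x) / ((ss_p_tot - ss_p_full) / df_res)
        if f_p >= f_obs - 1e-12:
            count += 1
    return {"F": float(f_obs), "p": (count + 1) / (int(n_perm) + 1),
            "df": m_x}


def varpart(Y, X_env, X_spatial, n_perm: int = 999,
            seed: Optional[int] = None) -> VarpartResult:
    """Partition response variation between environmental and spatial sets.

    Fractions (adjusted R2): [a] pure environment, [b] spatially structured
    environment, [c] pure space, [d] residual; [a]+[b]+[c]+[d] = 1 by
    construction.  [a] and [c] are tested with partial-RDA permutations,
    the unions [a+b], [b+c] and [a+b+c] with plain RDA permutations.
    [b] is not independently testable and is reported without a test.
    """
    env_names = list(X_env.columns) if isinstance(X_env, pd.DataFrame) else None
    spa_names = list(X_spatial.columns) if isinstance(X_spatial, pd.DataFrame) else None
    Yc = _center(_as_matrix(Y))
    E = _center(_as_matrix(X_env))
    S = _center(_as_matrix(X_spatial))
    if E.shape[1] == 0 or S.shape[1] == 0:
        raise ValueError("both predictor sets must be non-empty")
    if env_names and spa_names and set(env_names) & set(spa_names):
        warnings.warn("identical columns appear in both predictor sets",
                      stacklevel=2)
    n = Yc.shape[0]
    if n - (E.shape[1] + S.shape[1]) - 1 <= 0:
        raise ValueError(
            "too many predictors for the number of observations; pass "
            "forward-selected subsets")
    ss_total = float((Yc ** 2).sum())

    def _r2(X):
        return _fit_ss(Yc, X) / ss_total

    r2_env, r2_spa, r2_all = _r2(E), _r2(S), _r2(np.hstack([E, S]))
    adj_env = adjusted_r2(r2_env, n, E.shape[1])
    adj_spa = adjusted_r2(r2_spa, n, S.shape[1])
    adj_all = adjusted_r2(r2_all, n, E.shape[1] + S.shape[1])
    a = adj_all - adj_spa
    c = adj_all - adj_env
    b = adj_env + adj_spa - adj_all
    d = 1.0 - adj_all
    rng = np.random.default_rng(seed)

    def _plain_test(X):
        m = X.shape[1]
        ss_fit = _fit_ss(Yc, X)
        f_obs = (ss_fit / m) / ((ss_total - ss_fit) / (n - m - 1))
        count = 0
        for _ in range(int(n_perm)):
            Yp = Yc[rng.permutation(n)]
            ss_p = _fit_ss(Yp, X)
            if (ss_p / m) / ((ss_total - ss_p) / (n - m - 1)) >= f_obs - 1e-12:
                count += 1
        return {"F": float(f_obs), "p": (count + 1) / (int(n_perm) + 1),
                "df": m}

    tests = {
        "ab": _plain_test(E),
        "bc": _plain_test(S),
        "abc": _plain_test(np.hstack([E, S])),
        "a": _partial_rda_test(Yc, E, S, n_perm, rng),
        "c": _partial_rda_test(Yc, S, E, n_perm, rng),
    }
    fractions = {"a": a, "b": b, "c": c, "d": d,
                 "ab": adj_env, "bc": adj_spa, "abc": adj_all}
    raw = {"a": r2_all - r2_spa, "b": r2_env + r2_spa - r2_all,
           "c": r2_all - r2_env, "d": 1.0 - r2_all,
           "ab": r2_env, "bc": r2_spa, "abc": r2_all}
    return VarpartResult(fractions=fractions, raw_fractions=raw, tests=tests,
                         n_permutations=int(n_perm), seed=seed)
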