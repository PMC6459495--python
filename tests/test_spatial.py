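"""VIF screening, PCNM, RDA, forward selection and variation partitioning."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ecophylo import (
    forward_select,
    hellinger,
    pcnm,
    rda,
    remove_singletons,
    varpart,
    vif_screen,
)
from ecophylo.spatial import adjusted_r2


# ---------------------------------------------------------------------------
# Singleton removal and Hellinger


def test_remove_singletons_drops_single_occurrence_species():
    W = pd.DataFrame({"a": [1, 0, 0], "b": [3, 2, 0], "c": [0, 1, 0]},
                     index=["u1", "u2", "u3"])
    out = remove_singletons(W)
    assert list(out.columns) == ["b"]


def test_remove_singletons_identity_without_singletons(toy_community):
    out = remove_singletons(toy_community)
    pd.testing.assert_frame_equal(out, toy_community)


def test_remove_singletons_matches_planted_count():
    """A community with a known number of planted singletons loses exactly
    that many species (the survey itself reported 27)."""
    rng = np.random.default_rng(4)
    n_singletons = 27
    common = rng.integers(2, 10, size=(10, 40))
    W = pd.DataFrame(common, columns=[f"c{j}" for j in range(40)])
    for k in range(n_singletons):
        col = np.zeros(10, dtype=int)
        col[rng.integers(10)] = 1
        W[f"single{k}"] = col
    out = remove_singletons(W)
    assert W.shape[1] - out.shape[1] == n_singletons


def test_remove_singletons_all_singletons_rejected():
    W = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
    with pytest.raises(ValueError):
        remove_singletons(W)


def test_hellinger_rows_are_unit_vectors(toy_community):
    H = hellinger(toy_community)
    assert np.allclose((H ** 2).sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# VIF


def test_vif_orthogonal_variables_kept_with_unit_vif():
    n = 40
    x = np.tile([1.0, -1.0], n // 2)
    y = np.repeat([1.0, -1.0], n // 2)
    env = pd.DataFrame({"x": x, "y": y})
    kept, table = vif_screen(env, threshold=3.0)
    assert kept == ["x", "y"]
    assert table.iloc[-1]["x"] == pytest.approx(1.0, abs=1e-10)


def test_vif_duplicate_variable_removed_with_warning():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(30)
    env = pd.DataFrame({"x": x, "z": rng.standard_normal(30), "x2": x})
    with pytest.warns(UserWarning, match="collinearity"):
        kept, _ = vif_screen(env)
    assert "x2" not in kept  # later-listed duplicate goes first
    assert "x" in kept


def test_vif_matches_independent_least_squares_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    x1 = rng.standard_normal(50)
    x2 = rng.standard_normal(50)
    x3 = x1 + x2 + rng.normal(0, 0.3, 50)
    env = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    _, table = vif_screen(env, threshold=1e9)  # no removal, just the table
    fit = sm.OLS(x3, sm.add_constant(np.column_stack([x1, x2]))).fit()
    assert table.iloc[0]["x3"] == pytest.approx(1 / (1 - fit.rsquared), rel=1e-8)


def test_vif_order_independent_for_separated_vifs():
    rng = np.random.default_rng(2)
    x1 = rng.standard_normal(60)
    x2 = rng.standard_normal(60)
    hub = x1 * 2 + rng.normal(0, 0.2, 60)
    env = pd.DataFrame({"x1": x1, "hub": hub, "x2": x2})
    kept_a, _ = vif_screen(env)
    kept_b, _ = vif_screen(env[["x2", "hub", "x1"]])
    assert set(kept_a) == set(kept_b)


# ---------------------------------------------------------------------------
# PCNM


def _brute_force_pcnm(D):
    t = None
    # MST threshold by Prim's algorithm
    n = D.shape[0]
    in_tree = {0}
    edges = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and (best is None or D[i, j] < best[0]):
                    best = (D[i, j], j)
        edges.append(best[0])
        in_tree.add(best[1])
    t = max(edges)
    trunc = D.copy()
    trunc[trunc > t] = 4 * t
    np.fill_diagonal(trunc, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (trunc ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    return t, evals[order], evecs[:, order]


def test_pcnm_matches_brute_force_on_collinear_points():
    coords = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0] * 4},
                          index=list("abcd"))
    basis = pcnm(coords, projected=False)
    D = np.abs(coords["x"].to_numpy()[:, None] - coords["x"].to_numpy()[None, :])
    t, evals_ref, evecs_ref = _brute_force_pcnm(D)
    assert basis.truncation == pytest.approx(t)
    pos = evals_ref > 1e-8 * max(evals_ref.max(), 1.0)
    assert np.allclose(basis.eigenvalues, evals_ref[pos], atol=1e-8)
    for k in range(basis.n_vectors):
        a = basis.vectors.iloc[:, k].to_numpy()
        b = evecs_ref[:, k]
        assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


def test_pcnm_count_bound_and_orthogonality(default_study):
    basis = pcnm(default_study.coords)
    n = len(default_study.coords)
    assert basis.n_vectors <= n - 1
    G = basis.vectors.to_numpy().T @ basis.vectors.to_numpy()
    assert np.allclose(G, np.eye(basis.n_vectors), atol=1e-10)


def test_pcnm_duplicate_coordinates_rejected():
    coords = pd.DataFrame({"x": [0.0, 1.0, 1.0], "y": [0.0, 2.0, 2.0]})
    with pytest.raises(ValueError, match="duplicate"):
        pcnm(coords, projected=False)


# ---------------------------------------------------------------------------
# RDA


def test_rda_orthogonal_predictor_gives_zero_r2():
    n = 16
    y = np.tile([1.0, -1.0], n // 2)
    x = np.repeat([1.0, -1.0], n // 2)
    res = rda(y[:, None], x[:, None], n_perm=0)
    assert res.r2 == pytest.approx(0.0, abs=1e-12)


def test_rda_spanning_predictors_give_unit_r2():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((12, 3))
    B = rng.standard_normal((3, 5))
    Y = X @ B
    res = rda(Y, X, n_perm=0)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)
    assert res.adj_r2 <= 1.0


def test_rda_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    Y = rng.standard_normal((14, 6))
    X = pd.DataFrame(rng.standard_normal((14, 3)), columns=list("abc"))
    res = rda(Y, X, n_perm=99, seed=0)
    Yc = Y - Y.mean(axis=0)
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
    ss_fit = float((H @ Yc).ravel() @ (H @ Yc).ravel())
    ss_tot = float((Yc ** 2).sum())
    assert res.r2 == pytest.approx(ss_fit / ss_tot, abs=1e-10)
    n, m = 14, 3
    assert res.adj_r2 == pytest.approx(
        1 - (1 - ss_fit / ss_tot) * (n - 1) / (n - m - 1), abs=1e-10)


def test_rda_rank_deficient_predictors_dropped():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(15)
    X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(15)})
    with pytest.warns(UserWarning, match="rank-deficient"):
        res = rda(rng.standard_normal((15, 4)), X, n_perm=0)
    assert res.rank == 2
    assert "b" not in res.predictors


# ---------------------------------------------------------------------------
# Forward selection


def test_forward_select_alpha_one_orders_by_f():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
    Y = np.outer(X["b"], rng.standard_normal(5)) + 0.1 * rng.standard_normal((20, 5))
    res = forward_select(Y, X, alpha=1.0, n_perm=99, seed=0)
    assert set(res.selected) == {"a", "b", "c"}
    assert res.selected[0] == "b"  # strongest predictor enters first


def test_forward_select_planted_predictor_found_first():
    rng = np.random.default_rng(8)
    hits = 0
    for rep in range(40):
        X = pd.DataFrame(rng.standard_normal((18, 4)),
                         columns=["v1", "v2", "v3", "v4"])
        Y = np.outer(X["v3"], np.ones(6)) + 0.5 * rng.standard_normal((18, 6))
        res = forward_select(Y, X, alpha=0.05, n_perm=99,
                             seed=int(rng.integers(1 << 30)))
        hits += bool(res.selected) and res.selected[0] == "v3"
    assert hits / 40 >= 0.95


# ---------------------------------------------------------------------------
# Variation partitioning


def test_varpart_orthogonal_sets_have_zero_shared_fraction():
    n = 16
    e = np.tile([1.0, -1.0], n // 2)
    s = np.repeat([1.0, -1.0], n // 2)
    rng = np.random.default_rng(9)
    Y = np.outer(e, rng.standard_normal(4)) + np.outer(s, rng.standard_normal(4))
    res = varpart(Y, e[:, None], s[:, None], n_perm=99, seed=0)
    # exact additivity holds on the unadjusted scale; the adjusted shared
    # fraction carries only the degrees-of-freedom correction
    assert res.raw_fractions["b"] == pytest.approx(0.0, abs=1e-10)
    assert abs(res.fractions["b"]) < 0.1


def test_varpart_fractions_sum_to_one(default_study):
    rng = np.random.default_rng(10)
    W = default_study.community.groupby(default_study.parcels["site"]).sum()
    Y = hellinger(remove_singletons(W))
    env = default_study.env_regional[["annual_mean_temp"]]
    spa = pcnm(default_study.coords).vectors.iloc[:, :2]
    res = varpart(Y, env, spa, n_perm=99, seed=1)
    total = sum(res.fractions[k] for k in "abcd")
    assert total == pytest.approx(1.0, abs=1e-10)
    assert set(res.tests) == {"a", "c", "ab", "bc", "abc"}
    for t in res.tests.values():
        assert 0 < t["p"] <= 1


def test_varpart_planted_env_effect_lands_in_pure_env_fraction():
    rng = np.random.default_rng(11)
    n = 20
    env = rng.standard_normal((n, 1))
    spa = rng.standard_normal((n, 2))  # no real spatial signal
    Y = np.outer(env[:, 0], rng.standard_normal(6)) \
        + 0.4 * rng.standard_normal((n, 6))
    res = varpart(Y, env, spa, n_perm=99, seed=2)
    assert res.fractions["a"] > 0.4
    assert abs(res.fractions["c"]) < 0.1
    assert res.tests["a"]["p"] <= 0.05


def test_varpart_too_many_predictors_rejected():
    rng = np.random.default_rng(12)
    Y = rng.standard_normal((6, 3))
    with pytest.raises(ValueError, match="predictors"):
        varpart(Y, rng.standard_normal((6, 3)), rng.standard_normal((6, 3)),
                n_perm=99, seed=0)


def test_adjusted_r2_formula():
    assert adjusted_r2(0.5, 20, 3) == pytest.approx(1 - 0.5 * 19 / 16)
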