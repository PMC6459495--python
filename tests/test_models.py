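"""Random-intercept models, AICc ranking, conditional R2, factor tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from ecophylo import (
    CandidateModel,
    aicc_rank,
    build_candidates,
    conditional_r2,
    factor_comparison,
    fit_random_intercept,
)
from ecophylo.models import aicc


# ---------------------------------------------------------------------------
# Candidate enumeration


@pytest.mark.parametrize("n_vars,expected", [(1, 2), (2, 5), (4, 18)])
def test_candidate_counts(n_vars, expected):
    variables = [f"v{i}" for i in range(n_vars)]
    cands = build_candidates(variables, response="y", family="gaussian")
    assert len(cands) == expected
    names = [c.name for c in cands]
    assert "null" in names
    assert len(set(names)) == len(names)  # deduplicated


def test_candidate_interaction_terms_are_pairwise():
    cands = build_candidates(["a", "b", "c"], response="y", family="gaussian")
    inter = [c for c in cands if any(":" in t for t in c.terms)]
    assert len(inter) == 3
    for c in inter:
        assert len(c.terms) == 3  # a + b + a:b


def test_invalid_family_rejected():
    with pytest.raises(ValueError):
        CandidateModel(response="y", terms=(), family="binomial")


# ---------------------------------------------------------------------------
# Fitting oracles


def _grouped_frame(y, x, groups):
    return pd.DataFrame({"y": y, "x": x, "site": groups})


def test_gaussian_no_group_variance_matches_ols_oracle():
    """With zero between-site variance the ML fit collapses to OLS."""
    rng = np.random.default_rng(0)
    n = 60
    x = rng.standard_normal(n)
    y = 1.5 + 2.0 * x + rng.normal(0, 0.5, n)
    groups = np.repeat(np.arange(6), 10)
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=("x",), family="gaussian"),
        _grouped_frame(y, x, groups))
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit.sigma2_group < 0.05
    assert np.allclose(fit.fe_params, ols.params, atol=1e-3)


def test_gaussian_intercept_only_loglik_matches_closed_form():
    """At the sigma2_group = 0 boundary the ML log-likelihood equals the
    closed-form iid normal likelihood at its MLE."""
    rng = np.random.default_rng(1)
    y = rng.standard_normal(40)
    groups = np.repeat(np.arange(4), 10)
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=(), family="gaussian"),
        pd.DataFrame({"y": y, "site": groups}))
    s2 = y.var()
    closed = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
    assert fit.loglik >= closed - 1e-6  # random intercept can only help
    assert fit.loglik == pytest.approx(closed, abs=0.5)


def test_poisson_no_group_variance_matches_glm_oracle():
    rng = np.random.default_rng(2)
    n = 80
    x = rng.standard_normal(n)
    y = rng.poisson(np.exp(1.0 + 0.4 * x))
    groups = np.repeat(np.arange(8), 10)
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=("x",), family="poisson"),
        _grouped_frame(y, x, groups))
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
    assert np.allclose(fit.fe_params, glm.params, atol=5e-2)
    assert fit.loglik >= glm.llf - 1e-6  # GLM is the sigma = 0 submodel


def test_poisson_non_integer_response_rejected():
    df = pd.DataFrame({"y": [1.5, 2.0, 3.0, 1.0],
                       "site": ["a", "a", "b", "b"]})
    with pytest.raises(ValueError, match="integer"):
        fit_random_intercept(
            CandidateModel(response="y", terms=(), family="poisson"), df)


def test_poisson_slope_recovery_within_fifteen_percent():
    """Planted slope 0.1 per degC recovered on average over replicates."""
    rng = np.random.default_rng(3)
    betas = []
    for _ in range(60):
        temp = rng.normal(25, 2.0, 17)
        site = rng.integers(0, 9, 17)
        u = rng.normal(0, 0.2, 9)
        y = rng.poisson(np.exp(2.0 + 0.1 * (temp - 25) + u[site]))
        fit = fit_random_intercept(
            CandidateModel(response="y", terms=("temp",), family="poisson"),
            pd.DataFrame({"y": y, "temp": temp - 25, "site": site}))
        betas.append(fit.fe_params[1])
    assert np.mean(betas) == pytest.approx(0.1, rel=0.15)


def test_grouping_needs_two_levels():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "site": ["a", "a", "a"]})
    with pytest.raises(ValueError, match="levels"):
        fit_random_intercept(
            CandidateModel(response="y", terms=(), family="gaussian"), df)


# ---------------------------------------------------------------------------
# AICc


def test_aicc_arithmetic():
    # -2l + 2k = 100 at k = 3, n = 10 -> AICc = 100 + 24/6 = 104
    loglik = -(100 - 2 * 3) / 2
    assert aicc(loglik, 3, 10) == pytest.approx(104.0)


def test_aicc_approaches_aic_for_large_n():
    assert abs(aicc(-50.0, 4, 10_000_000) - (2 * 50 + 2 * 4)) < 1e-5


def test_identical_fits_share_weight(small_ensemble, default_study):
    from ecophylo.diversity import simpson_diversity

    tab = pd.DataFrame({"D": simpson_diversity(default_study.community)})
    tab = tab.join(default_study.parcels).dropna().reset_index()
    fit = fit_random_intercept(
        CandidateModel(response="D", terms=(), family="gaussian"), tab)
    table = aicc_rank([fit, fit])
    assert np.allclose(table["weight"], 0.5, atol=1e-10)
    assert table["weight"].sum() == pytest.approx(1.0, abs=1e-10)
    assert (table["delta_AICc"] <= 2).all()


def test_small_n_models_flagged_unrankable():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"y": rng.standard_normal(5),
                       "x": rng.standard_normal(5),
                       "site": ["a", "a", "b", "b", "b"]})
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=("x",), family="gaussian"), df)
    table = aicc_rank([fit])  # n = 5, k = 4 -> n <= k + 1
    assert not table["rankable"].iloc[0]
    assert np.isnan(table["AICc"].iloc[0])


def test_useless_predictor_never_decreases_loglik_and_null_wins():
    """ML monotonicity plus AICc's penalty under planted-null data."""
    rng = np.random.default_rng(5)
    null_best = 0
    R = 30
    for _ in range(R):
        n = 34
        site = np.repeat(np.arange(9), 4)[:n]
        y = rng.standard_normal(n) + rng.normal(0, 0.3, 9)[site]
        x = rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x, "site": site})
        f0 = fit_random_intercept(
            CandidateModel(response="y", terms=(), family="gaussian"), df)
        f1 = fit_random_intercept(
            CandidateModel(response="y", terms=("x",), family="gaussian"), df)
        assert f1.loglik >= f0.loglik - 1e-3  # optimizer tolerance
        table = aicc_rank([f0, f1])
        null_best += table.iloc[0]["model"] == "null"
    assert null_best / R >= 0.8


# ---------------------------------------------------------------------------
# Conditional R2


def test_conditional_r2_null_boundary_is_zero():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"y": rng.standard_normal(40),
                       "site": np.repeat(np.arange(4), 10)})
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=(), family="gaussian"), df)
    r2 = conditional_r2(fit)
    assert r2 == pytest.approx(0.0, abs=0.05)


def test_conditional_r2_noiseless_response_tends_to_one():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(40)
    df = pd.DataFrame({"y": 2 * x, "x": x,
                       "site": np.repeat(np.arange(4), 10)})
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=("x",), family="gaussian"), df)
    assert conditional_r2(fit) > 0.999


def test_conditional_r2_recovers_analytic_value():
    """Known variance components: R2c = (vf + vg) / (vf + vg + ve)."""
    rng = np.random.default_rng(8)
    vals = []
    beta, vg, ve = 1.0, 0.5, 1.0
    for _ in range(100):
        site = np.repeat(np.arange(10), 6)
        x = rng.standard_normal(60)
        y = beta * x + rng.normal(0, np.sqrt(vg), 10)[site] \
            + rng.normal(0, np.sqrt(ve), 60)
        fit = fit_random_intercept(
            CandidateModel(response="y", terms=("x",), family="gaussian"),
            pd.DataFrame({"y": y, "x": x, "site": site}))
        vals.append(conditional_r2(fit))
    truth = (beta ** 2 + vg) / (beta ** 2 + vg + ve)
    assert np.mean(vals) == pytest.approx(truth, abs=0.05)


def test_conditional_r2_poisson_variants():
    rng = np.random.default_rng(9)
    site = np.repeat(np.arange(6), 6)
    x = rng.standard_normal(36)
    y = rng.poisson(np.exp(1.5 + 0.3 * x))
    fit = fit_random_intercept(
        CandidateModel(response="y", terms=("x",), family="poisson"),
        pd.DataFrame({"y": y, "x": x, "site": site}))
    tri = conditional_r2(fit, poisson_variance="trigamma")
    logn = conditional_r2(fit, poisson_variance="lognormal")
    assert 0 <= tri <= 1 and 0 <= logn <= 1
    with pytest.raises(ValueError):
        conditional_r2(fit, poisson_variance="bogus")


# ---------------------------------------------------------------------------
# Factor comparisons


def test_factor_comparison_identical_levels_give_zero_contrast():
    rng = np.random.default_rng(10)
    base = rng.standard_normal(10)
    df = pd.DataFrame({
        "y": np.concatenate([base, base]),
        "f": ["A"] * 10 + ["B"] * 10,
        "site": list(range(10)) * 2,
    })
    fc = factor_comparison(df, response="y", factor="f", group="site",
                           family="gaussian", seed=0)
    assert fc.contrasts["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-6)


def test_factor_comparison_strong_shift_detected():
    """Three levels, one shifted by 3 SD: its contrasts are significant."""
    rng = np.random.default_rng(11)
    hits = 0
    R = 40
    for _ in range(R):
        n_per = 12
        y = np.concatenate([rng.standard_normal(n_per),
                            rng.standard_normal(n_per),
                            rng.standard_normal(n_per) + 3.0])
        df = pd.DataFrame({
            "y": y,
            "f": ["A"] * n_per + ["B"] * n_per + ["C"] * n_per,
            "site": np.tile(np.arange(6), 6),
        })
        fc = factor_comparison(df, response="y", factor="f", group="site",
                               family="gaussian", seed=1, n_mc=2000)
        sig = fc.contrasts[fc.contrasts["contrast"].str.contains("C")]
        hits += bool((sig["p_adj"] <= 0.05).all())
    assert hits / R >= 0.95


def test_factor_comparison_single_level_rejected(default_study):
    df = pd.DataFrame({"y": [1.0, 2.0], "f": ["A", "A"], "site": ["s", "t"]})
    with pytest.raises(ValueError):
        factor_comparison(df, response="y", factor="f", group="site")
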