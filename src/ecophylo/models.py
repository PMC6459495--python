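"""Random-intercept mixed models, AICc ranking, and conditional R2.

Diversity metrics are modelled against habitat or environmental predictors
with a site-level random intercept: ``y ~ fixed terms + (1|site)``.
Richness uses a Poisson family (log link), the remaining metrics Gaussian.
All models are estimated by maximum likelihood (not REML) so that AICc is
comparable across different fixed-effect structures.

The Gaussian fits are delegated to :class:`statsmodels` MixedLM with
``reml=False``.  The Poisson random-intercept marginal likelihood is
integrated by Gauss-Hermite quadrature over the site effect and maximised
numerically; no pre-installed Python library offers an ML Poisson GLMM, so
that likelihood is implemented here.

Candidate sets follow the survey's model-selection protocol: the null
(intercept-only) model, each single variable, each additive pair, each
two-variable interaction, and the complete additive model; candidates with
AICc within 2 of the best are flagged as the viable set.  Conditional R2
(variance explained by fixed plus random effects) uses the standard
variance-decomposition form, with a trigamma observation-level variance for
the Poisson family (lognormal variant available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "CandidateModel",
    "MixedFit",
    "build_candidates",
    "fit_random_intercept",
    "aicc_rank",
    "conditional_r2",
    "factor_comparison",
    "FactorComparison",
]


@dataclass(frozen=True)
class CandidateModel:
    """One candidate fixed-effect structure for a random-intercept model."""

    response: str
    terms: tuple            # e.g. ("hve", "trd", "hve:trd"); () is the null
    family: str             # "poisson" | "gaussian"
    group: str = "site"

    def __post_init__(self):
        if self.family not in ("poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        for t in self.terms:
            if ":" in t and len(t.split(":")) != 2:
                raise ValueError("interactions must involve exactly 2 variables")

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "null"


def build_candidates(variables: Sequence[str], response: str,
                     family: str, group: str = "site",
                     include_singles: bool = True) -> list:
    """Null + singles + additive pairs + interaction pairs + full model."""
    variables = list(variables)
    if len(variables) < 1:
        raise ValueError("need at least one variable")
    term_sets = [()]
    if include_singles:
        term_sets += [(v,) for v in variables]
    for a, b in combinations(variables, 2):
        term_sets.append((a, b))
        term_sets.append((a, b, f"{a}:{b}"))
    full = tuple(variables)
    if full not in term_sets:
        term_sets.append(full)
    seen, out = set(), []
    for terms in term_sets:
        if terms in seen:
            continue
        seen.add(terms)
        out.append(CandidateModel(response=response, terms=terms,
                                  family=family, group=group))
    return out


def _design(data: pd.DataFrame, terms: Sequence[str]):
    """Fixed-effects design matrix: intercept, main effects, products."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            cols.append(data[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class MixedFit:
    """Maximum-likelihood fit of one random-intercept model."""

    model: CandidateModel
    loglik: float
    k: int                      # parameter count incl. variance components
    fe_params: np.ndarray
    fe_names: tuple
    fe_cov: np.ndarray
    sigma2_group: float
    sigma2_resid: Optional[float]   # None for the Poisson family
    eta: np.ndarray                 # fixed-effect linear predictor
    n_obs: int
    boundary: bool
    converged: bool


def _ols_boundary_fit(X, names, y, model) -> MixedFit:
    """Gaussian ML at the sigma2_group = 0 boundary (plain least squares)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = float(resid @ resid) / n
    llf = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    XtX_inv = np.linalg.pinv(X.T @ X)
    return MixedFit(model=model, loglik=float(llf), k=X.shape[1] + 2,
                    fe_params=beta, fe_names=tuple(names),
                    fe_cov=XtX_inv * s2 * n / max(n - X.shape[1], 1),
                    sigma2_group=0.0, sigma2_resid=s2, eta=X @ beta,
                    n_obs=n, boundary=True, converged=True)


def _fit_gaussian(X, names, y, groups, model) -> MixedFit:
    ols = _ols_boundary_fit(X, names, y, model)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mlm = MixedLM(endog=y, exog=X, groups=groups)
        # keep the best optimum across optimizers: single-method fits can
        # stall a fraction of a log-likelihood unit short, which would break
        # nesting monotonicity across candidate models
        for method in (["lbfgs", "bfgs"], "powell"):
            try:
                cand = mlm.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                # typically a singular information matrix at the
                # sigma2_group -> 0 boundary
                continue
            if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf):
                res = cand
    if res is None or res.llf < ols.loglik - 1e-10:
        return ols
    sigma2_g = float(np.asarray(res.cov_re)[0, 0])
    sigma2_e = float(res.scale)
    boundary = sigma2_g < 1e-6 * max(sigma2_e, 1e-12)
    fe = np.asarray(res.fe_params)
    fe_cov = np.asarray(res.cov_params())[:len(fe), :len(fe)]
    return MixedFit(model=model, loglik=float(res.llf),
                    k=X.shape[1] + 2, fe_params=fe, fe_names=tuple(names),
                    fe_cov=fe_cov, sigma2_group=sigma2_g,
                    sigma2_resid=sigma2_e, eta=X @ fe, n_obs=len(y),
                    boundary=boundary, converged=bool(res.converged))


_GH_NODES = 31


def _poisson_loglik(params, X, y, group_idx, nodes, weights):
    """Marginal Poisson random-intercept log-likelihood via GH quadrature."""
    beta, sigma = params[:-1], abs(params[-1])
    eta = X @ beta
    # (groups, nodes) log-integrand, built by accumulating per-observation terms
    shift = sigma * nodes  # (K,)
    ll = 0.0
    for idx in group_idx:
        eta_g = eta[idx][:, None] + shift[None, :]       # (n_g, K)
        eta_g = np.clip(eta_g, -700, 700)                # keep exp finite
        contrib = (y[idx][:, None] * eta_g - np.exp(eta_g)).sum(axis=0)
        ll += special.logsumexp(np.log(weights) + contrib)
    ll -= special.gammaln(y + 1).sum()
    return ll


def _fit_poisson(X, names, y, groups, model) -> MixedFit:
    if not np.allclose(y, np.round(y)) or np.any(y < 0):
        raise ValueError("Poisson response must be non-negative integers")
    y = np.asarray(y, dtype=float)
    codes = pd.factorize(groups)[0]
    group_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    gh_x, gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
    nodes = np.sqrt(2.0) * gh_x
    weights = gh_w / np.sqrt(np.pi)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    start = np.append(np.asarray(glm.params), 0.3)

    def nll(p):
        return -_poisson_loglik(p, X, y, group_idx, nodes, weights)

    bounds = [(None, None)] * X.shape[1] + [(0.0, 8.0)]
    opt = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds)
    beta, sigma = opt.x[:-1], abs(opt.x[-1])
    boundary = sigma < 1e-4
    # fixed-effect covariance from the observed information (beta block)
    try:
        H = approx_hess1(opt.x, nll)
        fe_cov = np.linalg.inv(H)[:X.shape[1], :X.shape[1]]
    except np.linalg.LinAlgError:
        fe_cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return MixedFit(model=model, loglik=float(-opt.fun),
                    k=X.shape[1] + 1, fe_params=beta, fe_names=tuple(names),
                    fe_cov=fe_cov, sigma2_group=float(sigma ** 2),
                    sigma2_resid=None, eta=X @ beta, n_obs=len(y),
                    boundary=boundary, converged=bool(opt.success))


def fit_random_intercept(model: CandidateModel, data: pd.DataFrame) -> MixedFit:
    """ML fit of ``response ~ terms + (1|group)`` for one candidate."""
    groups = data[model.group].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ValueError("grouping factor needs at least 2 levels")
    y = data[model.response].to_numpy(dtype=float)
    X, names = _design(data, model.terms)
    if model.family == "gaussian":
        return _fit_gaussian(X, names, y, groups, model)
    return _fit_poisson(X, names, y, groups, model)


# ---------------------------------------------------------------------------
# AICc ranking


def aicc(loglik: float, k: int, n: int) -> float:
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_rank(fits: Sequence[MixedFit], n_obs: Optional[int] = None) -> pd.DataFrame:
    """Rank fits by small-sample AIC; viable set is delta AICc <= 2.

    Models with n <= k + 1 cannot be ranked (the correction diverges) and
    are flagged.  Akaike weights are normalised over rankable models.
    """
    if not fits:
        raise ValueError("no fits to rank")
    if n_obs is None:
        n_obs = fits[0].n_obs
    if any(f.n_obs != n_obs for f in fits):
        raise ValueError("fits are not all on identical data")
    rows = []
    for f in fits:
        rankable = n_obs > f.k + 1
        rows.append({
            "model": f.model.name,
            "family": f.model.family,
            "loglik": f.loglik,
            "k": f.k,
            "AICc": aicc(f.loglik, f.k, n_obs) if rankable else np.nan,
            "rankable": rankable,
            "conditional_r2": conditional_r2(f),
            "boundary": f.boundary,
        })
    table = pd.DataFrame(rows)
    best = table["AICc"].min()
    table["delta_AICc"] = table["AICc"] - best
    rel = np.exp(-0.5 * table["delta_AICc"].to_numpy())
    rel[~table["rankable"].to_numpy()] = 0.0
    table["weight"] = rel / np.nansum(rel)
    table["viable"] = table["delta_AICc"] <= 2.0
    return table.sort_values("AICc").reset_index(drop=True)


def conditional_r2(fit: MixedFit, poisson_variance: str = "trigamma") -> float:
    """Proportion of variance explained by fixed plus random effects.

    Gaussian: (var_fixed + sigma2_group) / (var_fixed + sigma2_group +
    sigma2_resid).  Poisson (log link): the observation-level variance is
    the trigamma function evaluated at the expected rate (lognormal
    approximation ``log(1 + 1/rate)`` behind the flag).
    """
    var_f = float(np.var(fit.eta))
    var_g = fit.sigma2_group
    if fit.model.family == "gaussian":
        denom = var_f + var_g + fit.sigma2_resid
        if denom <= 0:
            return np.nan
        return (var_f + var_g) / denom
    rate = float(np.exp(np.mean(fit.eta) + 0.5 * (var_f + var_g)))
    if poisson_variance == "trigamma":
        var_eps = float(special.polygamma(1, rate))
    elif poisson_variance == "lognormal":
        var_eps = float(np.log1p(1.0 / rate))
    else:
        raise ValueError("poisson_variance must be 'trigamma' or 'lognormal'")
    denom = var_f + var_g + var_eps
    if denom <= 0:
        return np.nan
    return (var_f + var_g) / denom


# ---------------------------------------------------------------------------
# Factor comparisons with post-hoc contrasts


@dataclass(frozen=True)
class FactorComparison:
    """Likelihood-ratio factor test plus single-step pairwise contrasts."""

    chi2: float
    df: int
    p_value: float
    contrasts: pd.DataFrame
    fit_full: MixedFit
    fit_null: MixedFit


def _dummy_data(data, response, factor, group):
    levels = sorted(pd.unique(data[factor].astype(str)))
    out = pd.DataFrame({response: data[response].to_numpy(),
                        group: data[group].to_numpy()})
    cols = []
    for lev in levels[1:]:
        col = f"{factor}[{lev}]"
        out[col] = (data[factor].astype(str) == lev).astype(float).to_numpy()
        cols.append(col)
    return out, levels, cols


def factor_comparison(data: pd.DataFrame, response: str, factor: str,
                      group: str = "site", family: str = "gaussian",
                      seed: int = 0, n_mc: int = 100_000) -> FactorComparison:
    """LR chi-square of a categorical factor and Tukey-style contrasts.

    The factor model ``y ~ factor + (1|group)`` is compared with the null
    by a likelihood-ratio chi-square.  Pairwise level differences are
    tested with z statistics from the fixed-effect covariance; the
    single-step (max-|z|) adjustment is evaluated by seeded Monte Carlo on
    the joint normal distribution of the contrast estimates.
    """
    levels = pd.unique(data[factor].astype(str))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    dummied, levels, cols = _dummy_data(data, response, factor, group)
    full = fit_random_intercept(
        CandidateModel(response=response, terms=tuple(cols), family=family,
                       group=group), dummied)
    null = fit_random_intercept(
        CandidateModel(response=response, terms=(), family=family,
                       group=group), dummied)
    chi2 = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = len(levels) - 1
    p = float(stats.chi2.sf(chi2, df))

    # contrast matrix over level means (treatment coding, ref = levels[0])
    name_idx = {nm: i for i, nm in enumerate(full.fe_names)}
    k = len(full.fe_params)
    mean_rows = []
    for lev in levels:
        row = np.zeros(k)
        row[name_idx["Intercept"]] = 1.0
        col = f"{factor}[{lev}]"
        if col in name_idx:
            row[name_idx[col]] = 1.0
        mean_rows.append(row)
    pairs, C = [], []
    for i, j in combinations(range(len(levels)), 2):
        pairs.append(f"{levels[i]} - {levels[j]}")
        C.append(mean_rows[i] - mean_rows[j])
    C = np.array(C)
    est = C @ full.fe_params
    cov = C @ full.fe_cov @ C.T
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, 0.0)
    corr = cov / np.outer(se, se)
    corr = np.nan_to_num((corr + corr.T) / 2.0, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(seed)
    # nearest-PSD safeguard for numerically indefinite correlation matrices
    evals, evecs = np.linalg.eigh(corr)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    draws = rng.standard_normal((n_mc, len(z))) @ L.T
    max_abs = np.abs(draws).max(axis=1)
    p_adj = np.array([(max_abs >= abs(zi)).mean() for zi in z])
    contrasts = pd.DataFrame({"contrast": pairs, "estimate": est, "se": se,
                              "z": z, "p_adj": p_adj})
    return FactorComparison(chi2=float(chi2), df=df, p_value=p,
                            contrasts=contrasts, fit_full=full, fit_null=null)
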