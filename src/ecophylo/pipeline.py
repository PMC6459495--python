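"""Config-driven orchestration of the two-scale analysis workflow.

``run_local`` analyses parcel-level data (forest vs grassland within
ecotones): tree-ensemble diversity metrics, habitat mixed-model tests,
per-habitat AICc candidate ranking, Bray-Curtis PCoA with PERMANOVA,
the PCPS taxa-shuffle ensemble test, and forward-selection RDA per habitat
after singleton removal.

``run_regional`` aggregates to sites (pooled occurrences; diversity
responses averaged over each site's ecotones): regional factor comparisons
and candidate ranking, site-level PCoA/PERMANOVA and PCPS ensemble test,
VIF screening of the regional environment, PCNM spatial eigenvectors,
forward selection for both predictor sets, and variation partitioning.

All randomness flows from one master seed through named substreams, so the
report is byte-identical across reruns and changing one stage's permutation
count does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .containers import validate_community_matrix
from .diversity import diversity_table
from .models import build_candidates, factor_comparison, fit_random_intercept, aicc_rank
from .ordination import bray_curtis, pcoa, permanova
from .pcps import pcps_ensemble_test
from .spatial import (forward_select, hellinger, pcnm, remove_singletons,
                      varpart, vif_screen)
from .synthetic import SyntheticStudy, generate_backbone
from .trees import graft_species, resolve_uncertainty

logger = logging.getLogger("ecophylo")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_local", "run_regional",
           "build_ensemble"]

METRIC_FAMILY = {"S": "poisson", "D": "gaussian",
                 "PD_mean": "gaussian", "PR_mean": "gaussian"}

LOCAL_VARIABLES = {
    "forest": ["temperature", "moisture", "litter_depth", "canopy_openness"],
    "grassland": ["temperature", "moisture", "veg_height", "shrub_density",
                  "tree_density"],
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Workflow defaults mirror the survey's analysis settings."""

    scale: str = "both"            # local | regional | both
    n_trees: int = 1000
    n_perm_adonis: int = 9999
    n_perm_shuffle: int = 9999
    n_perm_rda: int = 999
    alpha: float = 0.05
    vif_threshold: float = 3.0
    backbone_depth_myr: float = 140.0
    include_root_pd: bool = True
    seed: int = 0
    # optional cap on trees entering the per-tree taxa-shuffle loop (the
    # costliest stage); None analyses the full ensemble
    n_trees_pcps: Optional[int] = None

    def __post_init__(self):
        if self.scale not in ("local", "regional", "both"):
            raise ValueError("scale must be local, regional or both")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        for name in ("n_perm_adonis", "n_perm_shuffle", "n_perm_rda"):
            if getattr(self, name) < 99:
                raise ValueError(f"{name} must be >= 99")


@dataclass
class AnalysisReport:
    """Structured per-stage results with seed/permutation provenance."""

    scale: str
    config: dict
    sections: dict = field(default_factory=dict)

    def add(self, name: str, payload) -> None:
        self.sections[name] = payload

    def skip(self, name: str, reason: str) -> None:
        self.sections[name] = {"skipped": reason}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"scale": self.scale, "config": self.config,
                           "sections": self.sections},
                          indent=indent, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage(report, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            logger.info("stage %s: done in %.2fs", name,
                        time.perf_counter() - self.t0)
            return False
    return _Ctx()


def build_ensemble(study: SyntheticStudy, config: AnalysisConfig,
                   backbone=None):
    """Genus backbone -> species polytomy tree -> resolved ensemble."""
    if backbone is None:
        backbone = generate_backbone(study.genus_map,
                                     config.backbone_depth_myr,
                                     substream_seed(config.seed, "backbone"))
    poly = graft_species(backbone, study.genus_map)
    return resolve_uncertainty(poly, config.n_trees,
                               substream_seed(config.seed, "trees"))


def _perm_meta(result, seed_name, config):
    return {"n_permutations": result.n_permutations,
            "seed_substream": seed_name,
            "p_value": result.p_value}


def _rank_candidates(data, variables, response, family, report_rows, group="site"):
    cands = build_candidates(variables, response=response, family=family,
                             group=group)
    fits = [fit_random_intercept(c, data) for c in cands]
    return aicc_rank(fits)


def _nonconstant(df: pd.DataFrame, cols) -> list:
    return [c for c in cols if c in df.columns and df[c].nunique() > 1]


def _pcps_subset(ensemble, config: AnalysisConfig):
    if config.n_trees_pcps is None or config.n_trees_pcps >= len(ensemble):
        return ensemble
    from .trees import TreeEnsemble
    return TreeEnsemble(trees=ensemble.trees[:config.n_trees_pcps],
                        seed=ensemble.seed, source=ensemble.source)


def run_local(study: SyntheticStudy, config: AnalysisConfig = AnalysisConfig(),
              ensemble=None) -> AnalysisReport:
    """Local-scale analysis: habitats within ecotones (parcel units)."""
    validate_community_matrix(study.community)
    report = AnalysisReport(scale="local", config=dataclasses.asdict(config))
    W = study.community
    parcels = study.parcels
    habitat = parcels["habitat"]

    with _stage(report, "ensemble"):
        if ensemble is None:
            ensemble = build_ensemble(study, config)
        report.add("ensemble", {"n_trees": len(ensemble),
                                "n_tips": len(ensemble.tip_labels),
                                "seed_substream": "trees"})

    with _stage(report, "diversity"):
        table = diversity_table(W, ensemble,
                                include_root=config.include_root_pd)
        table = table.join(parcels[["habitat", "site", "ecotone", "region"]])
        report.add("diversity", {"table": table,
                                 "n_units": int(len(table)),
                                 "units_per_habitat":
                                     habitat.value_counts().to_dict()})

    with _stage(report, "habitat_tests"):
        tests = {}
        data = table.rename(columns={"habitat": "habitat_",})
        for metric, family in METRIC_FAMILY.items():
            fc = factor_comparison(table.reset_index(), response=metric,
                                   factor="habitat", group="site",
                                   family=family,
                                   seed=substream_seed(config.seed, f"fc_{metric}"))
            tests[metric] = {"chi2": fc.chi2, "df": fc.df, "p": fc.p_value}
        report.add("habitat_glmm", tests)

    with _stage(report, "candidate_ranking"):
        rankings = {}
        env_tables = {"forest": study.env_forest,
                      "grassland": study.env_grassland}
        vif_kept = {}
        for hab, env in env_tables.items():
            units = parcels.index[habitat == hab]
            kept, vtab = vif_screen(env.loc[units],
                                    threshold=config.vif_threshold)
            vif_kept[hab] = kept
            sub = table.loc[units].join(env.loc[units])
            sub = sub.reset_index()
            rankings[hab] = {}
            for metric, family in METRIC_FAMILY.items():
                rankings[hab][metric] = _rank_candidates(
                    sub, kept, metric, family, report)
        report.add("aicc_ranking",
                   {"vif_retained": vif_kept,
                    "tables": {h: {m: t for m, t in r.items()}
                               for h, r in rankings.items()}})

    with _stage(report, "taxonomic_composition"):
        bc = bray_curtis(W)
        ord_res = pcoa(bc)
        perm = permanova(bc, habitat.to_numpy(),
                         n_perm=config.n_perm_adonis,
                         seed=substream_seed(config.seed, "adonis_local"))
        report.add("pcoa_permanova", {
            "axis_proportions": ord_res.proportion_explained[:2],
            "first_two_axes_pct": float(100 * ord_res.proportion_explained[:2].sum()),
            "pseudo_F": perm.statistic, "p_value": perm.p_value, "r2": perm.r2,
            "n_permutations": perm.n_permutations,
            "seed_substream": "adonis_local"})

    with _stage(report, "phylogenetic_composition"):
        sub_ens = _pcps_subset(ensemble, config)
        pcps_rep = pcps_ensemble_test(
            W, sub_ens, habitat.to_numpy(), alpha=config.alpha,
            n_perm=config.n_perm_shuffle,
            seed=substream_seed(config.seed, "shuffle_local"))
        report.add("pcps", {
            "n_trees": pcps_rep.n_trees,
            "proportion_significant": pcps_rep.proportion_significant,
            "alpha": pcps_rep.alpha,
            "decision": pcps_rep.decision,
            "n_permutations": pcps_rep.n_permutations,
            "seed_substream": "shuffle_local",
            "p_value_range": [float(pcps_rep.p_values.min()),
                              float(pcps_rep.p_values.max())]})

    with _stage(report, "forward_selection"):
        fs = {}
        for hab in env_tables:
            units = parcels.index[habitat == hab]
            Wh = remove_singletons(W.loc[units])
            Wh = Wh.loc[Wh.sum(axis=1) > 0]  # units emptied by removal
            Y = hellinger(Wh)
            env = env_tables[hab].loc[Wh.index][vif_kept[hab]]
            res = forward_select(Y, env, alpha=config.alpha,
                                 n_perm=config.n_perm_rda,
                                 seed=substream_seed(config.seed, f"fs_{hab}"))
            fs[hab] = {"selected": list(res.selected), "table": res.table,
                       "n_species_after_singleton_removal": int(Wh.shape[1]),
                       "n_permutations": res.n_permutations,
                       "seed_substream": f"fs_{hab}"}
        report.add("forward_selection", fs)

    return report


def aggregate_sites(study: SyntheticStudy):
    """Pool occurrences per site; ecotone-mean diversity responses."""
    parcels = study.parcels
    W_site = study.community.groupby(parcels["site"]).sum()
    return W_site


def run_regional(study: SyntheticStudy,
                 config: AnalysisConfig = AnalysisConfig(),
                 ensemble=None) -> AnalysisReport:
    """Regional-scale analysis: sites within physiographic regions."""
    if len(study.coords) < 3:
        raise ValueError("regional analysis needs at least 3 sites")
    report = AnalysisReport(scale="regional", config=dataclasses.asdict(config))
    parcels = study.parcels
    site_region = parcels.drop_duplicates("site").set_index("site")["region"]

    with _stage(report, "ensemble"):
        if ensemble is None:
            ensemble = build_ensemble(study, config)
        report.add("ensemble", {"n_trees": len(ensemble),
                                "n_tips": len(ensemble.tip_labels)})

    with _stage(report, "aggregation"):
        W_site = aggregate_sites(study)
        # ecotone-level diversity, averaged per site
        W_eco = study.community.groupby(parcels["ecotone"]).sum()
        eco_table = diversity_table(W_eco, ensemble,
                                    include_root=config.include_root_pd)
        eco_site = parcels.drop_duplicates("ecotone").set_index("ecotone")["site"]
        site_table = eco_table.groupby(eco_site).mean()
        site_table["region"] = site_region.reindex(site_table.index)
        report.add("aggregation", {"n_sites": int(len(W_site)),
                                   "site_table": site_table})

    with _stage(report, "regional_factor_tests"):
        tests = {}
        df = site_table.reset_index().rename(columns={"index": "site"})
        for metric, family in METRIC_FAMILY.items():
            data = df.copy()
            if family == "poisson":
                data[metric] = np.round(data[metric]).astype(int)
            fc = factor_comparison(data, response=metric, factor="region",
                                   group="site", family=family,
                                   seed=substream_seed(config.seed,
                                                       f"rfc_{metric}"))
            tests[metric] = {"chi2": fc.chi2, "df": fc.df, "p": fc.p_value,
                             "contrasts": fc.contrasts}
        report.add("region_glmm", tests)

    with _stage(report, "vif"):
        kept, vtab = vif_screen(study.env_regional,
                                threshold=config.vif_threshold)
        report.add("vif", {"retained": kept,
                           "removed": [r for r in vtab["removed"] if r],
                           "threshold": config.vif_threshold})

    with _stage(report, "regional_ranking"):
        df = site_table.join(study.env_regional)
        rankings = {}
        for metric, family in METRIC_FAMILY.items():
            data = df.reset_index().rename(columns={"index": "site"})
            if family == "poisson":
                data[metric] = np.round(data[metric]).astype(int)
            rankings[metric] = _rank_candidates(data, kept, metric, family,
                                                report)
        report.add("aicc_ranking", rankings)

    with _stage(report, "taxonomic_composition"):
        bc = bray_curtis(W_site)
        ord_res = pcoa(bc)
        perm = permanova(bc, site_region.reindex(W_site.index).to_numpy(),
                         n_perm=config.n_perm_adonis,
                         seed=substream_seed(config.seed, "adonis_regional"))
        report.add("pcoa_permanova", {
            "axis_proportions": ord_res.proportion_explained[:2],
            "first_two_axes_pct": float(100 * ord_res.proportion_explained[:2].sum()),
            "pseudo_F": perm.statistic, "p_value": perm.p_value, "r2": perm.r2,
            "n_permutations": perm.n_permutations,
            "seed_substream": "adonis_regional"})

    with _stage(report, "phylogenetic_composition"):
        sub_ens = _pcps_subset(ensemble, config)
        pcps_rep = pcps_ensemble_test(
            W_site, sub_ens, site_region.reindex(W_site.index).to_numpy(),
            alpha=config.alpha, n_perm=config.n_perm_shuffle,
            seed=substream_seed(config.seed, "shuffle_regional"))
        report.add("pcps", {
            "n_trees": pcps_rep.n_trees,
            "proportion_significant": pcps_rep.proportion_significant,
            "alpha": pcps_rep.alpha,
            "decision": pcps_rep.decision,
            "n_permutations": pcps_rep.n_permutations,
            "seed_substream": "shuffle_regional"})

    with _stage(report, "spatial"):
        basis = pcnm(study.coords)
        Y = hellinger(remove_singletons(W_site))
        env = study.env_regional[kept]
        fs_env = forward_select(Y, env, alpha=config.alpha,
                                n_perm=config.n_perm_rda,
                                seed=substream_seed(config.seed, "fs_env"))
        fs_spa = forward_select(Y, basis.vectors, alpha=config.alpha,
                                n_perm=config.n_perm_rda,
                                seed=substream_seed(config.seed, "fs_spatial"))
        report.add("forward_selection", {
            "n_pcnm_vectors": basis.n_vectors,
            "pcnm_truncation_km": basis.truncation,
            "env_selected": list(fs_env.selected),
            "env_table": fs_env.table,
            "spatial_selected": list(fs_spa.selected),
            "spatial_table": fs_spa.table})

        # varpart uses the forward-selected subsets; if a set comes back
        # empty the top-F candidate stands in so the partition stays defined
        env_sel = list(fs_env.selected) or [fs_env.table["variable"].iloc[0]]
        spa_sel = list(fs_spa.selected) or [fs_spa.table["variable"].iloc[0]]
        vp = varpart(Y, env[env_sel], basis.vectors[spa_sel],
                     n_perm=config.n_perm_rda,
                     seed=substream_seed(config.seed, "varpart"))
        report.add("varpart", {
            "fractions": vp.fractions,
            "tests": vp.tests,
            "env_variables": env_sel,
            "env_fallback_used": not fs_env.selected,
            "spatial_variables": spa_sel,
            "spatial_fallback_used": not fs_spa.selected,
            "fraction_sum": vp.fractions["a"] + vp.fractions["b"]
            + vp.fractions["c"] + vp.fractions["d"]})

    return report
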