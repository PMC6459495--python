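"""Seed-reproducible synthetic ecotone studies.

The generator emulates a two-scale bait-transect survey of ant communities
in forest-grassland ecotones: nine sites in three physiographic regions,
two ecotones per site (one site with a single ecotone, 17 ecotones total),
one forest and one grassland parcel per ecotone, and fourteen baits per
parcel.  Species occurrence per parcel is Binomial over baits, with a
species-level logistic model for per-bait occupancy:

    occ[s, p] ~ Binomial(n_baits, logistic(alpha_s + habitat + covariates + spatial))

* ``alpha_s`` — species baseline logit, Normal(-5.5, 1.3).  These values were
  chosen so that a default draw resembles a real bait survey of this design:
  roughly 70-80 of 85 species detected, about 50% of detected species seen
  in a single habitat, a handful of singletons, and a most-frequent species
  occupying ~60-70 of the 476 baits.
* habitat term — specialist species (a configurable fraction) receive
  +/- half the habitat effect logit depending on their preferred habitat.
  Specialists can be assigned at random or clade-wise (whole genera share a
  preference), the latter planting a lineage-habitat association detectable
  by phylobetadiversity analysis.
* covariate terms — parcel temperature (forests), herbaceous vegetation
  height and treelet density (grasslands) act on the occupancy logit.
* spatial term — a Gaussian random field over site coordinates (exponential
  covariance) on each species' regional log-odds, producing spatially
  autocorrelated composition among regions.

Environmental covariates are Normal draws centred on the field study's
reported habitat means (grassland air temperature 29.9 degC, forest
24.8 degC).  Air moisture is generated strongly collinear with temperature
so that the variance-inflation screen has something to remove, as in the
original survey.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from scipy.special import expit

from .containers import validate_community_matrix

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "SyntheticStudy",
    "generate_study",
    "generate_backbone",
    "write_fixtures",
    "read_fixtures",
]

FOREST_TEMP_MEAN = 24.8   # degC, reported forest mean
GRASSLAND_TEMP_MEAN = 29.9  # degC, reported grassland mean


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: regions, sites, ecotones, habitats, baits, taxa."""

    n_regions: int = 3
    sites_per_region: int = 3
    ecotones_per_site: int = 2
    single_ecotone_site: bool = True  # one site contributes only one ecotone
    habitats: tuple = ("forest", "grassland")
    baits_per_parcel: int = 14
    n_species: int = 85
    n_genera: int = 23

    def __post_init__(self):
        for name in ("n_regions", "sites_per_region", "ecotones_per_site",
                     "baits_per_parcel", "n_species", "n_genera"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_genera > self.n_species:
            raise ValueError("n_genera cannot exceed n_species")
        if len(self.habitats) < 1:
            raise ValueError("at least one habitat required")

    @property
    def n_sites(self) -> int:
        return self.n_regions * self.sites_per_region

    def parcel_table(self) -> pd.DataFrame:
        """Enumerate parcels (one per habitat per ecotone)."""
        rows = []
        for r in range(self.n_regions):
            for s in range(self.sites_per_region):
                site_idx = r * self.sites_per_region + s
                n_eco = self.ecotones_per_site
                # mirror the survey: the middle region's last site has 1 ecotone
                if (self.single_ecotone_site and self.ecotones_per_site > 1
                        and r == self.n_regions // 2
                        and s == self.sites_per_region - 1):
                    n_eco = 1
                for e in range(n_eco):
                    for hab in self.habitats:
                        rows.append({
                            "parcel": f"r{r + 1}s{s + 1}e{e + 1}_{hab}",
                            "region": f"R{r + 1}",
                            "site": f"site{site_idx + 1:02d}",
                            "ecotone": f"r{r + 1}s{s + 1}e{e + 1}",
                            "habitat": hab,
                        })
        return pd.DataFrame(rows).set_index("parcel")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect sizes; all zeros defines the global null model."""

    habitat_specialist_fraction: float = 0.5
    habitat_effect_logit: float = 3.0
    temp_slope_forest: float = 0.1      # per degC on the occupancy logit
    hve_slope_grassland: float = -0.02  # per cm of herbaceous vegetation
    trd_slope_grassland: float = 0.15   # per treelet-density unit
    spatial_range_km: float = 200.0
    spatial_sd: float = 1.0
    specialists_by_clade: bool = False
    clade_baseline_logit: float = -5.0

    def __post_init__(self):
        if not 0.0 <= self.habitat_specialist_fraction <= 1.0:
            raise ValueError("habitat_specialist_fraction must lie in [0, 1]")
        if self.spatial_range_km <= 0:
            raise ValueError("spatial_range_km must be positive")
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be non-negative")

    @classmethod
    def null(cls) -> "EffectSpec":
        """All effect parameters zero (spatial field off)."""
        return cls(habitat_specialist_fraction=0.0, habitat_effect_logit=0.0,
                   temp_slope_forest=0.0, hve_slope_grassland=0.0,
                   trd_slope_grassland=0.0, spatial_sd=0.0)


@dataclass(frozen=True)
class SyntheticStudy:
    """One generated study: community, environment, coordinates, truth."""

    community: pd.DataFrame
    parcels: pd.DataFrame
    env_forest: pd.DataFrame
    env_grassland: pd.DataFrame
    env_regional: pd.DataFrame
    coords: pd.DataFrame
    genus_map: pd.Series
    truth: EffectSpec
    design: StudyDesign
    seed: int

    def __post_init__(self):
        validate_community_matrix(self.community)
        if self.community.to_numpy().max() > self.design.baits_per_parcel:
            raise ValueError("occurrence count exceeds baits per parcel")
        if sorted(self.genus_map.index) != sorted(self.community.columns):
            raise ValueError("genus map does not cover the species set")


def _genus_assignment(design: StudyDesign, rng) -> pd.Series:
    """Assign species to genera with a Zipf-skewed genus-size distribution."""
    g = design.n_genera
    genera = [f"g{i + 1:02d}" for i in range(g)]
    probs = 1.0 / np.arange(1, g + 1)
    probs /= probs.sum()
    # guarantee every genus is non-empty, then fill the rest by Zipf weights
    assignment = list(range(g))
    extra = rng.choice(g, size=design.n_species - g, p=probs)
    assignment.extend(extra.tolist())
    assignment = sorted(assignment)
    counter: dict = {}
    species, genus_of = [], []
    for gi in assignment:
        counter[gi] = counter.get(gi, 0) + 1
        species.append(f"{genera[gi]}_sp{counter[gi]:02d}")
        genus_of.append(genera[gi])
    return pd.Series(genus_of, index=pd.Index(species, name="species"),
                     name="genus")


def _site_coordinates(design: StudyDesign, rng) -> pd.DataFrame:
    """Decimal-degree site coordinates: regional clusters ~250-550 km apart."""
    centers = [(-55.0, -30.5), (-50.5, -29.0), (-53.0, -31.0)]
    rows = []
    sites = [f"site{i + 1:02d}" for i in range(design.n_sites)]
    for i, site in enumerate(sites):
        r = i // design.sites_per_region
        lon_c, lat_c = centers[r % len(centers)]
        rows.append({
            "site": site,
            "lon": lon_c + rng.uniform(-0.35, 0.35),
            "lat": lat_c + rng.uniform(-0.35, 0.35),
        })
    return pd.DataFrame(rows).set_index("site")


def km_distances(coords: pd.DataFrame) -> np.ndarray:
    """Inter-site distances in km via an equirectangular projection."""
    lat0 = np.deg2rad(coords["lat"].mean())
    x = np.deg2rad(coords["lon"].to_numpy()) * 6371.0 * np.cos(lat0)
    y = np.deg2rad(coords["lat"].to_numpy()) * 6371.0
    pts = np.column_stack([x, y])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _spatial_field(coords, effects: EffectSpec, n_species, rng) -> np.ndarray:
    """Per-species site effects from an exponential-covariance Gaussian field."""
    n_sites = len(coords)
    if effects.spatial_sd == 0:
        return np.zeros((n_species, n_sites))
    d = km_distances(coords)
    cov = effects.spatial_sd ** 2 * np.exp(-d / effects.spatial_range_km)
    cov += np.eye(n_sites) * 1e-9
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_species, n_sites))
    return z @ chol.T


def _regional_env(coords: pd.DataFrame, rng) -> pd.DataFrame:
    """Site-level climate/geomorphometry with built-in collinearity."""
    lat = coords["lat"].to_numpy()
    lon = coords["lon"].to_numpy()
    n = len(coords)
    # latent climate gradient decreasing to the northeast, as in the study
    # area; measured annual mean temperature carries its own station noise
    grad = 19.0 - 1.8 * (lat - lat.mean()) - 1.2 * (lon - lon.mean()) \
        + rng.normal(0, 0.35, n)
    amt = grad + rng.normal(0, 0.35, n)
    env = pd.DataFrame(index=coords.index)
    env["annual_mean_temp"] = amt
    tsea = rng.normal(4.5, 0.5, n)
    env["temp_seasonality"] = tsea
    # altitude tracks the gradient tightly (lapse rate); minimum temperature
    # of the coldest month blends both -- the collinear hub the VIF screen
    # is expected to remove first
    alt = 800.0 - 55.0 * (grad - grad.mean()) + 25.0 * (tsea - tsea.mean()) \
        + rng.normal(0, 12, n)
    env["min_temp_coldest"] = amt - 10.0 - 0.004 * (alt - alt.mean()) \
        + rng.normal(0, 0.2, n)
    env["annual_precip"] = rng.normal(1600, 150, n)
    env["precip_seasonality"] = rng.normal(12.0, 2.0, n)
    env["altitude"] = alt
    return env


def _clade_species(backbone, genus_map: pd.Series, target: int) -> set:
    """Species of a compact backbone clade of roughly the requested size.

    Among clades (including single genus tips) holding between half and
    twice the target species count, the one with the shallowest crown is
    chosen: a phylogenetically compact specialist clade is what makes a
    planted lineage-habitat association detectable, since fuzzy weighting
    pools species in proportion to their similarity.
    """
    from .trees import _node_heights

    sizes = genus_map.value_counts()
    heights, _ = _node_heights(backbone)
    candidates = []
    for node in backbone.preorder_node_iter():
        if node.parent_node is None:
            continue
        genera = [lf.taxon.label for lf in node.leaf_iter()]
        count = int(sum(sizes.get(g, 0) for g in genera))
        candidates.append((genera, count, heights[node]))
    eligible = [c for c in candidates if target / 2 <= c[1] <= 2 * target]
    if eligible:
        best = min(eligible, key=lambda c: c[2])[0]
    else:
        best = min(candidates, key=lambda c: abs(c[1] - target))[0]
    return set(genus_map.index[genus_map.isin(best)])


def generate_study(design: StudyDesign = StudyDesign(),
                   effects: EffectSpec = EffectSpec(),
                   seed: int = 0,
                   backbone=None) -> SyntheticStudy:
    """Draw one synthetic study under the given design and planted effects.

    With ``effects.specialists_by_clade`` a genus-level ``backbone`` tree
    must be supplied; the specialists are then the species of the backbone
    clade closest in size to the requested specialist fraction, all sharing
    the same habitat preference, which plants a lineage-habitat association.
    """
    rng = np.random.default_rng(seed)
    parcels = design.parcel_table()
    genus_map = _genus_assignment(design, rng)
    coords = _site_coordinates(design, rng)
    species = list(genus_map.index)
    n_sp = len(species)

    # --- environment ---------------------------------------------------
    is_forest = parcels["habitat"] == design.habitats[0]
    forest_parcels = parcels.index[is_forest]
    grass_parcels = parcels.index[~is_forest]
    envf = pd.DataFrame(index=forest_parcels)
    envf["temperature"] = rng.normal(FOREST_TEMP_MEAN, 2.0, len(forest_parcels))
    envf["moisture"] = 95.0 - 1.4 * envf["temperature"] + rng.normal(0, 0.8, len(forest_parcels))
    envf["litter_depth"] = np.clip(rng.normal(4.0, 1.5, len(forest_parcels)), 0.2, None)
    envf["canopy_openness"] = np.clip(rng.normal(18.0, 7.0, len(forest_parcels)), 1.0, 95.0)
    envg = pd.DataFrame(index=grass_parcels)
    envg["temperature"] = rng.normal(GRASSLAND_TEMP_MEAN, 2.0, len(grass_parcels))
    envg["moisture"] = 92.0 - 1.4 * envg["temperature"] + rng.normal(0, 0.8, len(grass_parcels))
    envg["veg_height"] = np.clip(rng.normal(30.0, 10.0, len(grass_parcels)), 3.0, None)
    envg["shrub_density"] = np.clip(rng.normal(5.0, 2.0, len(grass_parcels)), 0.0, None)
    envg["tree_density"] = np.clip(rng.normal(3.0, 1.5, len(grass_parcels)), 0.0, None)
    env_regional = _regional_env(coords, rng)

    # --- species-level parameters --------------------------------------
    alpha = rng.normal(-5.5, 1.3, n_sp)
    n_spec = int(round(effects.habitat_specialist_fraction * n_sp))
    specialist = np.zeros(n_sp, dtype=bool)
    pref_forest = np.zeros(n_sp, dtype=bool)
    if n_spec > 0:
        if effects.specialists_by_clade:
            if backbone is None:
                raise ValueError(
                    "specialists_by_clade requires a genus backbone tree")
            clade = _clade_species(backbone, genus_map, n_spec)
            for i, sp in enumerate(species):
                if sp in clade:
                    specialist[i] = True
                    pref_forest[i] = True
                    # exchangeable clade members: a shared moderate baseline
                    # gives every parcel its own random clade subsample,
                    # which is what makes the lineage signal detectable
                    alpha[i] = effects.clade_baseline_logit
        else:
            chosen = rng.choice(n_sp, size=n_spec, replace=False)
            specialist[chosen] = True
            pref_forest[chosen] = rng.random(n_spec) < 0.5

    site_effects = _spatial_field(coords, effects, n_sp, rng)
    site_index = {s: i for i, s in enumerate(coords.index)}

    # --- occupancy logits ----------------------------------------------
    n_parcels = len(parcels)
    eta = np.tile(alpha, (n_parcels, 1))
    hab_sign = np.where(is_forest.to_numpy()[:, None],
                        np.where(pref_forest[None, :], 1.0, -1.0),
                        np.where(pref_forest[None, :], -1.0, 1.0))
    eta += np.where(specialist[None, :],
                    hab_sign * effects.habitat_effect_logit / 2.0, 0.0)
    for p_i, parcel in enumerate(parcels.index):
        site = parcels.loc[parcel, "site"]
        eta[p_i] += site_effects[:, site_index[site]]
        if is_forest.loc[parcel]:
            eta[p_i] += effects.temp_slope_forest * (
                envf.loc[parcel, "temperature"] - FOREST_TEMP_MEAN)
        else:
            eta[p_i] += effects.hve_slope_grassland * (
                envg.loc[parcel, "veg_height"] - 30.0)
            eta[p_i] += effects.trd_slope_grassland * (
                envg.loc[parcel, "tree_density"] - 3.0)

    W = rng.binomial(design.baits_per_parcel, expit(eta))
    community = pd.DataFrame(W, index=parcels.index, columns=species)

    return SyntheticStudy(community=community, parcels=parcels,
                          env_forest=envf, env_grassland=envg,
                          env_regional=env_regional, coords=coords,
                          genus_map=genus_map, truth=effects, design=design,
                          seed=int(seed))


# ---------------------------------------------------------------------------
# Backbone generation


def generate_backbone(genus_map, depth_myr: float, seed: int,
                      shape: str = "coalescent") -> dendropy.Tree:
    """Random ultrametric genus tree of a given depth.

    ``shape="coalescent"`` builds the topology by uniform random pairwise
    joins with cumulative exponential coalescence steps, rescaled so every
    root-to-tip distance equals ``depth_myr`` exactly.  ``shape="balanced"``
    builds a ladder of even splits with node heights proportional to
    topological level, giving uniformly shallow genus stems — useful when a
    planted clade effect must stand on a clean similarity contrast.
    """
    if depth_myr <= 0:
        raise ValueError("depth_myr must be positive")
    genera = sorted(set(pd.Series(genus_map).values)) if not isinstance(
        genus_map, (list, tuple)) else sorted(set(genus_map))
    if len(genera) < 2:
        raise ValueError("need at least 2 genera to build a tree")
    rng = np.random.default_rng(seed)

    if shape == "balanced":
        return _balanced_backbone(genera, depth_myr, rng)
    if shape != "coalescent":
        raise ValueError("shape must be 'coalescent' or 'balanced'")

    tns = dendropy.TaxonNamespace()
    nodes = []
    for g in genera:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=g)
        nodes.append((node, 0.0))
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha) = nodes.pop(j)
        (nb, hb) = nodes.pop(i)
        parent = dendropy.Node()
        na.edge.length = height - ha
        nb.edge.length = height - hb
        parent.add_child(na)
        parent.add_child(nb)
        nodes.append((parent, height))
    root, root_height = nodes[0]
    scale = depth_myr / root_height
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    return tree


def _balanced_backbone(genera, depth_myr, rng) -> dendropy.Tree:
    """Even recursive splits; node height proportional to topological level."""
    import math

    tns = dendropy.TaxonNamespace()
    order = list(genera)
    rng.shuffle(order)
    levels = math.ceil(math.log2(len(order)))

    def build(labels):
        node = dendropy.Node()
        if len(labels) == 1:
            node.taxon = tns.require_taxon(label=labels[0])
            return node, 0
        half = len(labels) // 2
        left, hl = build(labels[:half])
        right, hr = build(labels[half:])
        level = max(hl, hr) + 1
        h_node = depth_myr * level / levels
        for child, h_child in ((left, hl), (right, hr)):
            child.edge.length = h_node - depth_myr * h_child / levels
            node.add_child(child)
        return node, level

    root, _ = build(order)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    # stretch the root to the full depth if the split tree is shallower
    heights = {}
    for n in tree.postorder_node_iter():
        heights[n] = 0.0 if n.is_leaf() else max(
            heights[c] + c.edge.length for c in n.child_nodes())
    if heights[root] < depth_myr:
        for c in root.child_nodes():
            c.edge.length += depth_myr - heights[root]
    return tree


# ---------------------------------------------------------------------------
# Fixture I/O


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def write_fixtures(study: SyntheticStudy, directory, backbone=None) -> dict:
    """Write a study to TSV/Newick/YAML files; returns the path map."""
    from . import trees as _trees

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    validate_community_matrix(study.community)
    paths = {
        "community": directory / "community.tsv",
        "parcels": directory / "parcels.tsv",
        "env_forest": directory / "env_forest.tsv",
        "env_grassland": directory / "env_grassland.tsv",
        "env_regional": directory / "env_regional.tsv",
        "coords": directory / "coords.tsv",
        "genus_map": directory / "genus_map.tsv",
        "truth": directory / "truth.yaml",
    }
    _write_tsv(study.community, paths["community"], "parcel")
    _write_tsv(study.parcels, paths["parcels"], "parcel")
    _write_tsv(study.env_forest, paths["env_forest"], "parcel")
    _write_tsv(study.env_grassland, paths["env_grassland"], "parcel")
    _write_tsv(study.env_regional, paths["env_regional"], "site")
    _write_tsv(study.coords, paths["coords"], "site")
    _write_tsv(study.genus_map.to_frame(), paths["genus_map"], "species")
    truth = {"seed": study.seed,
             "design": dataclasses.asdict(study.design),
             "effects": dataclasses.asdict(study.truth)}
    truth["design"]["habitats"] = list(truth["design"]["habitats"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    if backbone is not None:
        paths["backbone"] = directory / "backbone.nwk"
        _trees.write_newick(backbone, paths["backbone"])
    return paths


def read_fixtures(directory) -> SyntheticStudy:
    """Read a study back from :func:`write_fixtures` output."""
    directory = Path(directory)

    def _read(name, index_col):
        return pd.read_csv(directory / name, sep="\t", index_col=index_col)

    community = _read("community.tsv", "parcel")
    parcels = _read("parcels.tsv", "parcel")
    with open(directory / "truth.yaml", encoding="utf-8") as fh:
        truth = yaml.safe_load(fh)
    design_kw = dict(truth["design"])
    design_kw["habitats"] = tuple(design_kw["habitats"])
    return SyntheticStudy(
        community=community,
        parcels=parcels,
        env_forest=_read("env_forest.tsv", "parcel"),
        env_grassland=_read("env_grassland.tsv", "parcel"),
        env_regional=_read("env_regional.tsv", "site"),
        coords=_read("coords.tsv", "site"),
        genus_map=_read("genus_map.tsv", "species")["genus"],
        truth=EffectSpec(**truth["effects"]),
        design=StudyDesign(**design_kw),
        seed=int(truth["seed"]),
    )
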