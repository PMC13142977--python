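"""Synthetic-world generator with known ground truth.

Generates the full data constellation the analysis pipeline consumes:
geohistorical areas, nested language families, languages with binary and
categorical structural features, populations with SNP genotypes under
controllable autozygosity, and per-cell covariates — all on a geodesic
hexagonal grid, with every generating parameter recorded.

The genetic–linguistic coupling is latent: a single smooth "isolation" field
over cells raises population autozygosity (lowering genetic diversity) and
widens the dispersion of cell-level feature-state intercepts (raising
expected feature entropy).  The two data types are conditionally independent
given that field; neither is computed from the other.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .geogrid import Grid, lonlat_to_unit, unit_to_lonlat, EARTH_RADIUS_KM


@dataclass(frozen=True)
class WorldConfig:
    """Generating parameters for a synthetic world.

    Scales mimic the real study's structure at desk size: ten geohistorical
    areas, a few hundred grid cells holding languages, nested families, a
    median of eight genotyped individuals per population.
    """

    n_areas: int = 10
    n_families: int = 24
    taxonomy_depth: int = 3
    n_languages: int = 500
    n_features_binary: int = 36
    categorical_state_counts: tuple = (3, 4, 6, 7)
    n_populations: int = 60
    individuals_per_population: int = 8   # median, Poisson-distributed
    n_snps: int = 2000
    # hierarchical variance components of the feature-state model
    sigma_area: float = 0.6
    sigma_cell: float = 0.4
    sigma_family: float = 0.9
    sigma_population: float = 0.3         # population noise on logit f
    alpha_sd: float = 0.8                 # spread of global feature baselines
    # smooth spatial structure
    spatial_length_scale_km: float = 3000.0
    spatial_sd: float = 0.5
    richness_concentration: float = 1.0   # SD of the log-intensity field
    family_scale_km: float = 3000.0
    # latent coupling: isolation -> autozygosity and -> feature dispersion
    coupling_beta_f: float = 0.5          # isolation on log cell dispersion
    isolation_to_f: float = 0.8           # isolation on logit autozygosity
    base_f: float = 0.05
    # covariate modulation of cell-level feature dispersion
    beta_r: float = 0.0
    beta_t: float = 0.0
    beta_p1: float = 0.0
    beta_p2: float = 0.0
    beta_d: float = 0.0
    # nuisance
    missing_rate_features: float = 0.3
    missing_rate_genotypes: float = 0.02
    allele_freq_beta: tuple = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_families > max(self.n_languages, 1):
            raise ValueError("more families than languages")
        if any(j < 2 for j in self.categorical_state_counts):
            raise ValueError("categorical features need at least 2 states")
        if not (0.0 <= self.base_f < 1.0):
            raise ValueError("base autozygosity must lie in [0, 1)")
        for name in ("sigma_area", "sigma_cell", "sigma_family",
                     "sigma_population", "spatial_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def feature_ids(self):
        nb = self.n_features_binary
        return ([f"B{k:03d}" for k in range(nb)]
                + [f"C{k:03d}" for k in range(len(self.categorical_state_counts))])


@dataclass
class SyntheticWorld:
    config: WorldConfig
    languages: pd.DataFrame
    individuals: pd.DataFrame
    populations: pd.DataFrame
    genotypes: np.ndarray          # (n_individuals, n_snps), NaN = missing
    covariates: pd.DataFrame
    truth: dict

    # ------------------------------------------------------------------
    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.languages.to_csv(out / "languages.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.populations.to_csv(out / "populations.csv", index=False)
        self.individuals.to_csv(out / "individuals.csv", index=False)
        gt = pd.DataFrame(
            self.genotypes,
            index=self.individuals["individual_id"],
            columns=[f"snp{j}" for j in range(self.genotypes.shape[1])])
        gt.to_csv(out / "genotypes.tsv", sep="\t", na_rep="NA")
        write_plink_text(self.genotypes, self.individuals, out / "genotypes")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not serializable: {type(x)}")


def write_plink_text(genotypes, individuals, prefix):
    """PLINK-text (.ped/.map) export; alleles coded A (ref) / B (alt)."""
    prefix = Path(prefix)
    n_snp = genotypes.shape[1]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(n_snp):
            fh.write(f"1\tsnp{j}\t0\t{j + 1}\n")
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, row in enumerate(np.asarray(genotypes, dtype=float)):
            ind = individuals.iloc[i]
            geno = "\t".join(code.get(g, "0 0") for g in row)
            fh.write(f"{ind['population']}\t{ind['individual_id']}"
                     f"\t0\t0\t0\t-9\t{geno}\n")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def gaussian_random_field(points_xyz: np.ndarray, length_scale_km: float,
                          sd: float, rng) -> np.ndarray:
    """Squared-exponential GRF over points on the sphere (chordal distance)."""
    n = len(points_xyz)
    if n == 0:
        return np.zeros(0)
    d = np.linalg.norm(points_xyz[:, None, :] - points_xyz[None, :, :],
                       axis=-1) * EARTH_RADIUS_KM
    cov = sd ** 2 * np.exp(-0.5 * (d / max(length_scale_km, 1e-9)) ** 2)
    cov[np.diag_indices(n)] += 1e-8 + 1e-6 * sd ** 2
    return np.linalg.cholesky(cov) @ rng.standard_normal(n)


def _standardize(x):
    s = x.std()
    return (x - x.mean()) / s if s > 1e-12 else x - x.mean()


def _farthest_point_sample(points_xyz, k, rng):
    idx = [int(rng.integers(len(points_xyz)))]
    d = 1.0 - points_xyz @ points_xyz[idx[0]]
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, 1.0 - points_xyz @ points_xyz[nxt])
    return np.array(idx)


def define_areas(grid: Grid, n_areas: int, seed: int) -> np.ndarray:
    """Contiguous continent-scale areas: nearest of n_areas far-apart seeds."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    xyz = lonlat_to_unit([c.centroid_lon for c in grid.cells],
                         [c.centroid_lat for c in grid.cells])
    seeds = _farthest_point_sample(xyz, n_areas, rng)
    sims = xyz @ xyz[seeds].T
    return np.array([f"area{a:02d}" for a in np.argmax(sims, axis=1)])


# ---------------------------------------------------------------------------
# generator stages
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig, grid: Grid) -> SyntheticWorld:
    """Generate a complete synthetic world on the given grid."""
    root = np.random.SeedSequence([config.seed, 2026])
    rng_lang, rng_feat, rng_gen, rng_cov = (
        np.random.default_rng(s) for s in root.spawn(4))

    cells_xyz = lonlat_to_unit([c.centroid_lon for c in grid.cells],
                               [c.centroid_lat for c in grid.cells])
    cell_ids = np.array([c.cell_id for c in grid.cells])
    area_of_cell = define_areas(grid, config.n_areas, config.seed)

    # latent isolation field (standardized over all cells)
    isolation = _standardize(gaussian_random_field(
        cells_xyz, config.spatial_length_scale_km, 1.0, rng_lang)) \
        if grid.n_cells else np.zeros(0)

    languages = _generate_languages(config, grid, cells_xyz, cell_ids,
                                    area_of_cell, rng_lang)
    truth = {
        "config": dataclasses.asdict(config),
        "isolation_by_cell": dict(zip(cell_ids, isolation)),
        "area_of_cell": dict(zip(cell_ids, area_of_cell)),
    }

    world = SyntheticWorld(config=config, languages=languages,
                           individuals=None, populations=None, genotypes=None,
                           covariates=None, truth=truth)
    world._grid_cache = (grid, cells_xyz, cell_ids, area_of_cell, isolation)

    feature_truth = generate_feature_states(world, config, rng=rng_feat)
    truth["features"] = feature_truth
    pops, inds, genos, gen_truth = _generate_populations_and_genotypes(
        config, grid, cells_xyz, cell_ids, area_of_cell, isolation,
        languages, rng_gen)
    world.populations = pops
    world.individuals = inds
    world.genotypes = genos
    truth["populations"] = gen_truth
    world.covariates = generate_covariates(world, config, rng=rng_cov)
    return world


def _generate_languages(config, grid, cells_xyz, cell_ids, area_of_cell, rng):
    n = config.n_languages
    cols = ["language_id", "lon", "lat", "family", "taxonomy_path", "area",
            "cell_id"]
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    # uneven per-cell language counts through a smooth log-intensity field
    log_int = gaussian_random_field(cells_xyz, config.spatial_length_scale_km,
                                    config.richness_concentration, rng)
    w = np.exp(log_int - log_int.max())
    w /= w.sum()
    cell_of_lang = rng.choice(grid.n_cells, size=n, p=w)
    # place languages inside their cell (jitter around the centroid)
    lon0 = np.array([grid.cells[c].centroid_lon for c in cell_of_lang])
    lat0 = np.array([grid.cells[c].centroid_lat for c in cell_of_lang])
    radius = np.array([grid.cells[c].diameter_km for c in cell_of_lang]) * 0.25
    from .geogrid import jitter_points
    lon, lat = jitter_points(lon0, lat0,
                             float(radius.max()) if len(radius) else 0.0,
                             seed=int(rng.integers(2 ** 31)))
    # keep each language in its sampled cell: re-assign jittered points and
    # fall back to the centroid when the jitter crossed a boundary
    assigned = grid.assign_points(lon, lat)
    moved = assigned != cell_ids[cell_of_lang]
    lon[moved], lat[moved] = lon0[moved], lat0[moved]

    # families: spatially coherent soft assignment around family centres
    k = min(config.n_families, n)
    centre_idx = rng.choice(n, size=k, replace=False)
    centres = lonlat_to_unit(lon[centre_idx], lat[centre_idx])
    pts = lonlat_to_unit(lon, lat)
    chord = np.linalg.norm(pts[:, None, :] - centres[None, :, :], axis=-1) \
        * EARTH_RADIUS_KM
    logits = -0.5 * (chord / config.family_scale_km) ** 2
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    fam_idx = np.array([rng.choice(k, p=p) for p in probs])
    families = np.array([f"fam{j:03d}" for j in fam_idx])
    # nested branches inside each family
    paths = np.empty(n, dtype=object)
    for j in range(k):
        members = np.nonzero(fam_idx == j)[0]
        if config.taxonomy_depth >= 3 and len(members) > 1:
            n_branch = max(1, int(np.ceil(np.sqrt(len(members)) / 1.5)))
            br = rng.integers(n_branch, size=len(members))
        else:
            br = np.zeros(len(members), dtype=int)
        for m, b in zip(members, br):
            paths[m] = f"fam{j:03d}/br{b:02d}/L{m:04d}"
    return pd.DataFrame({
        "language_id": [f"L{m:04d}" for m in range(n)],
        "lon": lon, "lat": lat, "family": families,
        "taxonomy_path": paths,
        "area": area_of_cell[cell_of_lang],
        "cell_id": cell_ids[cell_of_lang],
    })


def generate_feature_states(world: SyntheticWorld, config: WorldConfig, *,
                            rng=None) -> dict:
    """Draw feature states in place from the hierarchical logistic model.

    Cell-level intercepts for each feature are drawn with SD
    sigma_cell * exp(coupling_beta_f * isolation + covariate modulation), so
    positive coupling widens local state dispersion — hence raises expected
    entropy — exactly where isolation is high.  Returns the truth record.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2026, 1]))
    grid, cells_xyz, cell_ids, area_of_cell, isolation = world._grid_cache
    langs = world.languages
    n = len(langs)
    truth = {}
    if n == 0:
        for fid in config.feature_ids:
            world.languages[fid] = pd.Series(dtype=float)
        return truth

    cell_pos = grid.cell_index(langs["cell_id"].to_numpy())
    area_codes, area_levels = pd.factorize(langs["area"], sort=True)
    fam_codes, fam_levels = pd.factorize(langs["family"], sort=True)
    log_disp = config.coupling_beta_f * isolation
    truth["log_dispersion_modifier_by_cell"] = dict(zip(cell_ids, log_disp))

    state_counts = ([2] * config.n_features_binary
                    + list(config.categorical_state_counts))
    for fid, j_states in zip(config.feature_ids, state_counts):
        n_free = j_states - 1
        alpha = rng.normal(0.0, config.alpha_sd, n_free)
        a_area = rng.normal(0.0, config.sigma_area, (len(area_levels), n_free))
        a_fam = rng.normal(0.0, config.sigma_family, (len(fam_levels), n_free))
        cell_sd = config.sigma_cell * np.exp(log_disp)
        a_cell = rng.normal(0.0, 1.0, (grid.n_cells, n_free)) \
            * cell_sd[:, None]
        sfield = np.column_stack([
            gaussian_random_field(cells_xyz, config.spatial_length_scale_km,
                                  config.spatial_sd, rng)
            for _ in range(n_free)]) if config.spatial_sd > 0 else \
            np.zeros((grid.n_cells, n_free))
        eta = (alpha[None, :] + a_area[area_codes] + a_fam[fam_codes]
               + a_cell[cell_pos] + sfield[cell_pos])
        eta_full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        eta_full -= eta_full.max(axis=1, keepdims=True)
        p = np.exp(eta_full)
        p /= p.sum(axis=1, keepdims=True)
        states = (p.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)
        vals = states.astype(float)
        miss = rng.random(n) < config.missing_rate_features
        vals[miss] = np.nan
        world.languages[fid] = vals
        truth[fid] = {"n_states": j_states, "alpha": alpha,
                      "sigma_cell_base": config.sigma_cell}
    return truth


def _generate_populations_and_genotypes(config, grid, cells_xyz, cell_ids,
                                        area_of_cell, isolation, languages,
                                        rng):
    n_pop = config.n_populations
    if n_pop == 0:
        pops = pd.DataFrame(columns=["population", "cell_id", "area", "lon",
                                     "lat", "true_f"])
        inds = pd.DataFrame(columns=["individual_id", "population", "lon",
                                     "lat", "cell_id", "area"])
        return pops, inds, np.zeros((0, config.n_snps)), {}
    # sample population cells favouring cells that hold languages
    counts = pd.Series(languages["cell_id"]).value_counts() \
        if len(languages) else pd.Series(dtype=float)
    w = np.array([counts.get(cid, 0.0) + 0.5 for cid in cell_ids])
    w /= w.sum()
    pop_cells = rng.choice(grid.n_cells, size=n_pop, p=w)
    base_logit = logit(max(config.base_f, 1e-4))
    true_f = expit(base_logit + config.isolation_to_f * isolation[pop_cells]
                   + config.sigma_population * rng.standard_normal(n_pop))
    pops = pd.DataFrame({
        "population": [f"pop{k:03d}" for k in range(n_pop)],
        "cell_id": cell_ids[pop_cells],
        "area": area_of_cell[pop_cells],
        "lon": [grid.cells[c].centroid_lon for c in pop_cells],
        "lat": [grid.cells[c].centroid_lat for c in pop_cells],
        "true_f": true_f,
    })
    sizes = np.maximum(2, rng.poisson(config.individuals_per_population,
                                      n_pop))
    rows = []
    for k in range(n_pop):
        for i in range(sizes[k]):
            rows.append({"individual_id": f"pop{k:03d}_i{i:02d}",
                         "population": f"pop{k:03d}",
                         "lon": pops["lon"][k], "lat": pops["lat"][k],
                         "cell_id": pops["cell_id"][k],
                         "area": pops["area"][k]})
    inds = pd.DataFrame(rows)
    pop_of_ind = np.repeat(np.arange(n_pop), sizes)
    genos = generate_genotypes_matrix(
        true_f, pop_of_ind, config.n_snps, rng,
        allele_freq_beta=config.allele_freq_beta,
        missing_rate=config.missing_rate_genotypes)
    truth = {"true_f_by_population": dict(zip(pops["population"], true_f)),
             "sizes": sizes}
    return pops, inds, genos, truth


def generate_genotypes_matrix(f_by_pop, pop_of_individual, n_snps, rng, *,
                              allele_freq_beta=(2.0, 2.0),
                              missing_rate=0.0) -> np.ndarray:
    """Genotypes under per-population autozygosity f.

    At each SNP an individual is autozygous with probability f (homozygous
    for an allele drawn by its population frequency) and otherwise a
    Hardy–Weinberg draw.  Frequencies are Beta draws per population x SNP.
    """
    f_by_pop = np.asarray(f_by_pop, dtype=float)
    if np.any((f_by_pop < 0) | (f_by_pop >= 1)):
        raise ValueError("autozygosity must lie in [0, 1)")
    pop_of_individual = np.asarray(pop_of_individual)
    n_ind = len(pop_of_individual)
    a, b = allele_freq_beta
    p = rng.beta(a, b, size=(len(f_by_pop), n_snps))
    p_ind = p[pop_of_individual]                    # (n_ind, n_snps)
    f_ind = f_by_pop[pop_of_individual][:, None]
    auto = rng.random((n_ind, n_snps)) < f_ind
    hom_alt = rng.random((n_ind, n_snps)) < p_ind
    g_auto = np.where(hom_alt, 2.0, 0.0)
    allele1 = rng.random((n_ind, n_snps)) < p_ind
    allele2 = rng.random((n_ind, n_snps)) < p_ind
    g_hw = allele1.astype(float) + allele2.astype(float)
    g = np.where(auto, g_auto, g_hw)
    if missing_rate > 0:
        g[rng.random((n_ind, n_snps)) < missing_rate] = np.nan
    return g


def generate_covariates(world: SyntheticWorld, config: WorldConfig, *,
                        rng=None) -> pd.DataFrame:
    """Per-cell covariate table for cells holding at least one language.

    Log richness is counted from the language table (not simulated);
    taxonomic diversity uses the surrogate effective-branch index; the two
    environmental PCs and log population density are smooth spatial fields.
    All columns except the raw counts are centred and scaled across cells.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2026, 3]))
    grid, cells_xyz, cell_ids, area_of_cell, isolation = world._grid_cache
    langs = world.languages
    if len(langs) == 0:
        return pd.DataFrame(columns=["cell_id", "n_languages", "log_richness",
                                     "taxonomic_diversity", "pc1", "pc2",
                                     "log_density"])
    from .regression import taxonomic_diversity
    occupied = np.sort(langs["cell_id"].unique())
    counts = langs.groupby("cell_id").size()
    taxdiv = langs.groupby("cell_id")["taxonomy_path"].apply(
        lambda s: taxonomic_diversity(s.tolist()))
    pos = grid.cell_index(occupied)
    pc1 = _standardize(gaussian_random_field(
        cells_xyz, config.spatial_length_scale_km, 1.0, rng)[pos])
    pc2 = _standardize(gaussian_random_field(
        cells_xyz, config.spatial_length_scale_km, 1.0, rng)[pos])
    dens = gaussian_random_field(
        cells_xyz, config.spatial_length_scale_km, 1.0, rng)[pos]
    return pd.DataFrame({
        "cell_id": occupied,
        "n_languages": counts.loc[occupied].to_numpy(),
        "log_richness": np.log(counts.loc[occupied].to_numpy(dtype=float)),
        "taxonomic_diversity": taxdiv.loc[occupied].to_numpy(dtype=float),
        "pc1": pc1, "pc2": pc2,
        "log_density": _standardize(dens),
        "isolation": isolation[pos],
    })
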