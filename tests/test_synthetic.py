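import json

import numpy as np
import pandas as pd
import pytest

from hexdiv.geogrid import GridSpec, build_grid
from hexdiv.synthetic import (WorldConfig, generate_genotypes_matrix,
                              generate_world)


class TestWorldConfig:
    def test_more_families_than_languages_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(n_languages=5, n_families=10)

    def test_invalid_state_count_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(categorical_state_counts=(1,))

    def test_autozygosity_bounds(self):
        with pytest.raises(ValueError):
            WorldConfig(base_f=1.0)
        with pytest.raises(ValueError):
            generate_genotypes_matrix([1.2], [0], 10,
                                      np.random.default_rng(0))


class TestGenerateWorld:
    def test_empty_language_table_is_valid(self, coarse_grid):
        cfg = WorldConfig(n_languages=0, n_families=0, n_populations=4,
                          individuals_per_population=4, n_snps=50, seed=1)
        world = generate_world(cfg, coarse_grid)
        assert len(world.languages) == 0
        assert len(world.individuals) > 0

    def test_determinism_under_seed(self, coarse_grid):
        cfg = WorldConfig(n_languages=80, n_features_binary=2,
                          categorical_state_counts=(), n_populations=6,
                          n_snps=60, n_families=10, seed=9)
        w1 = generate_world(cfg, coarse_grid)
        w2 = generate_world(cfg, coarse_grid)
        pd.testing.assert_frame_equal(w1.languages, w2.languages)
        pd.testing.assert_frame_equal(w1.covariates, w2.covariates)
        assert np.array_equal(w1.genotypes, w2.genotypes, equal_nan=True)

    def test_every_unit_mapped_to_one_cell_and_area(self, small_world):
        langs = small_world.languages
        assert langs["cell_id"].notna().all()
        assert langs["area"].notna().all()
        inds = small_world.individuals
        assert inds["cell_id"].notna().all()
        # each cell belongs to exactly one area
        per_cell = langs.groupby("cell_id")["area"].nunique()
        assert (per_cell == 1).all()

    def test_genotype_codes(self, small_world):
        g = small_world.genotypes
        vals = g[~np.isnan(g)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}

    def test_population_median_size_realistic(self, small_world):
        sizes = small_world.individuals.groupby("population").size()
        assert 5 <= sizes.median() <= 11

    def test_truth_record_roundtrips_json(self, small_world, tmp_path):
        small_world.write(tmp_path)
        with open(tmp_path / "truth.json") as fh:
            truth = json.load(fh)
        assert truth["config"]["seed"] == small_world.config.seed
        assert len(truth["populations"]["true_f_by_population"]) == \
            len(small_world.populations)
        # text outputs exist
        for fn in ("languages.csv", "genotypes.tsv", "genotypes.ped",
                   "genotypes.map", "covariates.csv"):
            assert (tmp_path / fn).exists()

    def test_plink_text_roundtrip(self, small_world, tmp_path):
        small_world.write(tmp_path)
        ped = open(tmp_path / "genotypes.ped").read().strip().split("\n")
        assert len(ped) == len(small_world.individuals)
        first = ped[0].split("\t")
        assert first[0] == small_world.individuals["population"].iloc[0]


class TestFeatureStates:
    def test_null_model_gives_half_frequency(self, coarse_grid):
        cfg = WorldConfig(n_languages=4000, n_features_binary=1,
                          categorical_state_counts=(), n_families=10,
                          n_populations=2, n_snps=10, sigma_area=0.0,
                          sigma_cell=0.0, sigma_family=0.0, alpha_sd=0.0,
                          spatial_sd=0.0, coupling_beta_f=0.0,
                          missing_rate_features=0.0, seed=12)
        world = generate_world(cfg, coarse_grid)
        freq = world.languages["B000"].mean()
        assert abs(freq - 0.5) < 3.0 / np.sqrt(4000)

    def test_family_concordance_dominates_when_family_sd_large(
            self, coarse_grid):
        cfg = WorldConfig(n_languages=800, n_features_binary=6,
                          categorical_state_counts=(), n_families=20,
                          n_populations=2, n_snps=10, sigma_area=0.1,
                          sigma_cell=0.1, sigma_family=3.0, alpha_sd=0.0,
                          spatial_sd=0.1, missing_rate_features=0.0, seed=13)
        world = generate_world(cfg, coarse_grid)
        langs = world.languages
        # within-family concordance of feature states should beat the
        # between-family baseline
        rates = []
        for fid in [f"B{k:03d}" for k in range(6)]:
            fam_mean = langs.groupby("family")[fid].mean()
            within = (fam_mean ** 2 + (1 - fam_mean) ** 2).mean()
            p = langs[fid].mean()
            between = p ** 2 + (1 - p) ** 2
            rates.append(within - between)
        assert np.mean(rates) > 0.05

    def test_categorical_states_within_range(self, small_world):
        col = small_world.languages["C000"].dropna()
        assert col.between(0, 2).all()  # three states coded 0..2

    def test_missingness_rate_applied(self, small_world):
        rate = small_world.languages["B000"].isna().mean()
        assert 0.15 < rate < 0.45  # configured 0.3


class TestGenotypes:
    def test_extreme_autozygosity_mostly_homozygous(self):
        rng = np.random.default_rng(3)
        g = generate_genotypes_matrix([0.995], np.zeros(30, dtype=int), 400,
                                      rng)
        hom = np.isin(g, (0.0, 2.0))[~np.isnan(g)].mean()
        assert hom > 0.98

    def test_heterozygosity_matches_theory(self):
        # per-population heterozygosity ~ (1 - f) E[2p(1-p)] under
        # Beta(2,2) frequencies: E[2pq] = 2 * (2*2)/((4)*(5)) = 0.4
        rng = np.random.default_rng(4)
        for f in (0.0, 0.4):
            g = generate_genotypes_matrix([f], np.zeros(80, dtype=int), 3000,
                                          rng)
            het = (g == 1.0).mean()
            assert abs(het - (1 - f) * 0.4) < 0.02


class TestCovariates:
    def test_log_richness_is_recount(self, small_world):
        cov = small_world.covariates.set_index("cell_id")
        counts = small_world.languages.groupby("cell_id").size()
        assert np.allclose(cov["log_richness"],
                           np.log(counts.loc[cov.index]))

    def test_single_language_cell_zero_log_richness(self, small_world):
        cov = small_world.covariates
        singles = cov[cov["n_languages"] == 1]
        if len(singles):
            assert np.allclose(singles["log_richness"], 0.0)

    def test_smooth_fields_standardized(self, small_world):
        cov = small_world.covariates
        for col in ("pc1", "pc2", "log_density"):
            assert abs(cov[col].mean()) < 1e-9
            assert abs(cov[col].std() - 1.0) < 0.2

    def test_isolation_field_raises_entropy_dispersion(self, coarse_grid):
        # with strong coupling, cells in isolated regions receive wider
        # cell-level intercepts, hence more extreme local state frequencies
        cfg = WorldConfig(n_languages=1500, n_features_binary=12,
                          categorical_state_counts=(), n_families=12,
                          n_populations=2, n_snps=10, sigma_area=0.0,
                          sigma_family=0.0, sigma_cell=0.8, alpha_sd=0.0,
                          spatial_sd=0.0, coupling_beta_f=1.2,
                          missing_rate_features=0.0, seed=21)
        world = generate_world(cfg, coarse_grid)
        iso = world.truth["isolation_by_cell"]
        langs = world.languages
        disp = []
        for cid, grp in langs.groupby("cell_id"):
            if len(grp) < 6:
                continue
            dev = np.mean([abs(grp[f"B{k:03d}"].mean() - 0.5)
                           for k in range(12)])
            disp.append((iso[cid], dev))
        disp = np.array(disp)
        r = np.corrcoef(disp[:, 0], disp[:, 1])[0, 1]
        assert r > 0.15
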