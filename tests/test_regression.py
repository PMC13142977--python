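import numpy as np
import pandas as pd
import pytest

from hexdiv.regression import (MODEL_LADDER, ModelSpec, build_dataset,
                               compare_models, marginal_slopes,
                               simulate_regression_dataset,
                               taxonomic_diversity)
from hexdiv._gibbs import fit_model_gibbs


class TestModelLadder:
    def test_ladder_composition(self):
        assert MODEL_LADDER["m1"] == ("r", "t")
        assert set(MODEL_LADDER["m5"]) == {"r", "t", "p1", "p2", "d"}
        assert set(MODEL_LADDER["m8"]) == set(("r", "t", "p1", "p2", "d",
                                               "f"))
        for name, preds in MODEL_LADDER.items():
            assert {"r", "t"} <= set(preds)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("m9")


class TestTaxonomicDiversity:
    def test_single_language_scores_one(self):
        assert taxonomic_diversity(["famA/br00/L1"]) == pytest.approx(1.0)

    def test_k_singleton_families_score_k(self):
        paths = [f"fam{k}/br00/L{k}" for k in range(5)]
        assert taxonomic_diversity(paths) == pytest.approx(5.0)

    def test_new_family_beats_sister_dialect(self):
        base = ["famA/br00/L1", "famA/br01/L2", "famB/br00/L3"]
        with_sister = base + ["famA/br01/L2b"]
        with_new_family = base + ["famC/br00/L4"]
        gain_sister = taxonomic_diversity(with_sister) \
            - taxonomic_diversity(base)
        gain_family = taxonomic_diversity(with_new_family) \
            - taxonomic_diversity(base)
        assert gain_family > gain_sister

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            taxonomic_diversity([])


class TestBuildDataset:
    @pytest.fixture(scope="class")
    def tables(self):
        cells = [f"c{k:04d}" for k in range(8)]
        rng = np.random.default_rng(0)
        ent = pd.DataFrame([
            {"feature_id": f, "cell_id": c, "mean_logit_hn": rng.normal(),
             "sd_logit_hn": 0.2}
            for f in ("F1", "F2", "F3") for c in cells[:6]])
        fc = pd.DataFrame({
            "cell_id": cells[2:],
            "area": ["a1", "a1", "a2", "a2", "a2", "a2"],
            "mean_f": rng.normal(size=6), "sd_f": 0.1})
        cov = pd.DataFrame({
            "cell_id": cells,
            "log_richness": rng.normal(size=8) + 1,
            "taxonomic_diversity": np.exp(rng.normal(size=8)),
            "pc1": rng.normal(size=8), "pc2": rng.normal(size=8),
            "log_density": rng.normal(size=8)})
        return ent, fc, cov

    def test_join_arithmetic(self, tables, coarse_grid):
        ent, fc, cov = tables
        # linguistic cells c0..c5, genetic cells c2..c7 -> overlap c2..c5
        ent2 = ent.copy()
        ent2["cell_id"] = ent2["cell_id"].map(
            dict(zip([f"c{k:04d}" for k in range(8)],
                     [c.cell_id for c in coarse_grid.cells[:8]])))
        fc2 = fc.copy()
        fc2["cell_id"] = fc2["cell_id"].map(
            dict(zip([f"c{k:04d}" for k in range(8)],
                     [c.cell_id for c in coarse_grid.cells[:8]])))
        cov2 = cov.copy()
        cov2["cell_id"] = cov2["cell_id"].map(
            dict(zip([f"c{k:04d}" for k in range(8)],
                     [c.cell_id for c in coarse_grid.cells[:8]])))
        rows = build_dataset(ent2, fc2, cov2, coarse_grid)
        assert len(rows) == 3 * 4
        # predictors centred over unique cells
        per_cell = rows.groupby("cell_id").first()
        for col in ("r", "t", "p1", "p2", "d", "f_obs"):
            assert abs(per_cell[col].mean()) < 1e-9

    def test_disjoint_cells_rejected(self, tables, coarse_grid):
        ent, fc, cov = tables
        ids = [c.cell_id for c in coarse_grid.cells]
        ent2 = ent.copy()
        ent2["cell_id"] = ids[0]
        fc2 = fc.copy()
        fc2["cell_id"] = ids[100]
        cov2 = cov.copy()
        cov2["cell_id"] = ids[100]
        with pytest.raises(ValueError, match="no cells"):
            build_dataset(ent2, fc2, cov2, coarse_grid)


@pytest.fixture(scope="module")
def strong_effect_fits():
    """m1 and m4 Gibbs fits on data with a strong genetic effect."""
    rows, truth = simulate_regression_dataset(
        n_cells=25, n_features=8, n_areas=3, seed=33,
        beta={"r": 0.2, "t": -0.1, "f": 0.8}, predictors=("r", "t", "f"),
        tau_feat=np.array([0.3, 0.15, 0.15, 0.15]),
        tau_area=np.array([0.2, 0.05, 0.05, 0.05]),
        y_sd_mean=0.15, f_sd_mean=0.1)
    spec4 = ModelSpec("m4", use_spline=False)
    spec1 = ModelSpec("m1", use_spline=False)
    f4 = fit_model_gibbs(spec4, rows, n_warmup=300, n_draws=1200, seed=2,
                         check_convergence=False, diagnostics=False)
    f1 = fit_model_gibbs(spec1, rows, n_warmup=300, n_draws=1200, seed=3,
                         check_convergence=False, diagnostics=False)
    return rows, truth, f1, f4


class TestFitAndCompare:
    def test_strong_effect_recovered(self, strong_effect_fits):
        _, truth, _, f4 = strong_effect_fits
        bf = f4.posterior.stacked("beta_f")
        assert (bf > 0).mean() >= 0.98
        assert abs(bf.mean() - 0.8) < 0.35

    def test_loo_prefers_model_with_f(self, strong_effect_fits):
        _, _, f1, f4 = strong_effect_fits
        cmp = compare_models({"m1": f1, "m4": f4})
        assert cmp.iloc[0]["model"] == "m4"
        worse = cmp[cmp["model"] == "m1"].iloc[0]
        assert worse["d_elpd_vs_best"] > 2.0 * worse["d_se"]

    def test_model_compared_with_itself_zero_delta(self, strong_effect_fits):
        _, _, _, f4 = strong_effect_fits
        cmp = compare_models({"a": f4, "b": f4})
        assert np.allclose(cmp["d_elpd_vs_best"], 0.0)

    def test_mismatched_datasets_rejected(self, strong_effect_fits):
        rows2, _ = simulate_regression_dataset(
            n_cells=10, n_features=4, n_areas=2, seed=99,
            predictors=("r", "t"))
        spec1 = ModelSpec("m1", use_spline=False)
        other = fit_model_gibbs(spec1, rows2, n_warmup=100, n_draws=100,
                                seed=1, check_convergence=False,
                                diagnostics=False)
        _, _, f1, _ = strong_effect_fits
        with pytest.raises(ValueError, match="different datasets"):
            compare_models({"m1": f1, "other": other})

    def test_marginal_slopes_structure(self, strong_effect_fits):
        _, _, _, f4 = strong_effect_fits
        by_feat = marginal_slopes(f4, "feature")
        by_area = marginal_slopes(f4, "area")
        assert len(by_feat) == 8 and len(by_area) == 3
        for col in ("mean", "p_positive", "hpdi89_lower", "hpdi89_upper",
                    "excludes_zero_89"):
            assert col in by_feat.columns
        # strong positive effect: most groups should exclude zero upward
        assert by_area["p_positive"].min() > 0.8

    def test_slopes_require_f_in_model(self, strong_effect_fits):
        _, _, f1, _ = strong_effect_fits
        with pytest.raises(ValueError):
            marginal_slopes(f1, "feature", predictor="f")

    def test_p_positive_is_one_for_all_positive_draws(self,
                                                      strong_effect_fits):
        _, _, _, f4 = strong_effect_fits
        sl = marginal_slopes(f4, "area")
        bf = f4.posterior.stacked("beta_f")
        dev = f4.posterior.stacked("eff_area")[..., 1 + 2]
        for g in range(3):
            expected = float(((bf + dev[:, g]) > 0).mean())
            assert sl["p_positive"].iloc[g] == pytest.approx(expected)


class TestMeasurementError:
    def test_flip_invariance_of_f(self):
        # replacing F_obs by (1 - scaled F) exactly negates the slope
        rows, _ = simulate_regression_dataset(
            n_cells=20, n_features=12, n_areas=2, seed=8,
            beta={"r": 0.1, "t": 0.0, "f": 0.5}, predictors=("r", "t", "f"),
            tau_feat=np.full(4, 0.1), tau_area=np.full(4, 0.05),
            y_sd_mean=0.15, f_sd_mean=0.1)
        spec = ModelSpec("m4", use_spline=False)
        f_a = fit_model_gibbs(spec, rows, n_warmup=200, n_draws=800, seed=5,
                              check_convergence=False, diagnostics=False)
        flipped = rows.copy()
        flipped["f_obs"] = 1.0 - flipped["f_obs"]
        f_b = fit_model_gibbs(spec, flipped, n_warmup=200, n_draws=800,
                              seed=5, check_convergence=False,
                              diagnostics=False)
        a = f_a.posterior.stacked("beta_f")
        b = f_b.posterior.stacked("beta_f")
        # same posterior up to sign (within MC error)
        assert abs(a.mean() + b.mean()) < 0.08
        assert 0.7 < a.std() / b.std() < 1.4

    def test_inflating_y_sd_widens_posterior(self):
        rows, _ = simulate_regression_dataset(
            n_cells=20, n_features=20, n_areas=2, seed=10,
            beta={"r": 0.1, "t": 0.0, "f": 0.4}, predictors=("r", "t", "f"),
            tau_feat=np.full(4, 0.1), tau_area=np.full(4, 0.05),
            y_sd_mean=0.25, f_sd_mean=0.1)
        spec = ModelSpec("m4", use_spline=False)
        tight = fit_model_gibbs(spec, rows, n_warmup=250, n_draws=1000,
                                seed=6, check_convergence=False,
                                diagnostics=False)
        wide_rows = rows.copy()
        wide_rows["y_sd"] = rows["y_sd"] * 4.0
        wide = fit_model_gibbs(spec, wide_rows, n_warmup=250, n_draws=1000,
                               seed=6, check_convergence=False,
                               diagnostics=False)
        assert wide.posterior.stacked("beta_f").std() \
            > tight.posterior.stacked("beta_f").std()

    def test_shrinking_y_sd_approaches_plain_fit(self):
        rows, _ = simulate_regression_dataset(
            n_cells=12, n_features=5, n_areas=2, seed=14, y_sd_mean=0.3,
            beta={"r": 0.2, "t": 0.0, "f": 0.3}, predictors=("r", "t", "f"),
            tau_feat=np.full(4, 0.1), tau_area=np.full(4, 0.05))
        spec = ModelSpec("m4", use_spline=False)
        small = rows.copy()
        small["y_sd"] = 1e-4
        tiny = rows.copy()
        tiny["y_sd"] = 1e-6
        fa = fit_model_gibbs(spec, small, n_warmup=250, n_draws=800, seed=7,
                             check_convergence=False, diagnostics=False)
        fb = fit_model_gibbs(spec, tiny, n_warmup=250, n_draws=800, seed=7,
                             check_convergence=False, diagnostics=False)
        assert abs(fa.posterior.stacked("beta_f").mean()
                   - fb.posterior.stacked("beta_f").mean()) < 0.05
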