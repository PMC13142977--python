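"""Checks of the inference machinery itself: reverse-mode gradients, NUTS on
known targets, the LKJ canonical-partial-correlation construction, and
agreement between the independent sampling strategies on one dataset."""

import numpy as np
import pytest
from scipy import stats

from hexdiv import _ad as ad
from hexdiv._bayes import _cpc_matrices, halfnormal_sd, lkj_cholesky
from hexdiv._nuts import sample_nuts


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(15)
        A = rng.standard_normal((6, 15))
        idx = np.array([0, 1, 1, 3, 4, 14])

        def f(v):
            y = A @ v
            z = ad.gather(v, idx)
            m = ad.stack([y, y * 2.0, ad.tanh(y)], axis=1)
            q = ad.cumsum((v * v).reshape(3, 5), axis=1)
            return (ad.log1pexp(y).sum() + ad.sumsq(z)
                    + ad.logsumexp(m, axis=1).sum()
                    + ad.exp(q * 0.05).sum()
                    + ad.sqrt(ad.exp(v)).sum()
                    + ad.absolute(v).sum() * 0.1
                    + ad.neg_half_sumsq(v))

        vg = ad.value_and_grad(f)
        _, g = vg(x)
        num = np.array([(vg(x + 1e-6 * e)[0] - vg(x - 1e-6 * e)[0]) / 2e-6
                        for e in np.eye(15)])
        assert np.abs(g - num).max() < 1e-6

    def test_matmul_both_sides(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 3))
        b = rng.standard_normal((3, 5))
        x = rng.standard_normal(12)

        def f(v):
            m = v.reshape(4, 3)
            return ((m @ b) * (a @ b)).sum() + (a.T @ m).sum()

        vg = ad.value_and_grad(f)
        _, g = vg(x)
        num = np.array([(vg(x + 1e-6 * e)[0] - vg(x - 1e-6 * e)[0]) / 2e-6
                        for e in np.eye(12)])
        assert np.abs(g - num).max() < 1e-6


class TestNUTS:
    def test_correlated_gaussian_moments(self):
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        prec = np.linalg.inv(cov)
        mu = np.array([1.0, -2.0])

        def lp(x):
            d = x - mu
            return -0.5 * d @ prec @ d, -prec @ d

        draws, _ = sample_nuts(lp, 2, n_chains=2, n_warmup=500, n_draws=1500,
                               seed=3)
        flat = draws.reshape(-1, 2)
        assert np.abs(flat.mean(0) - mu).max() < 0.1
        assert np.abs(np.cov(flat.T) - cov).max() < 0.25

    def test_reproducible_under_seed(self):
        def lp(x):
            return -0.5 * x @ x, -x

        d1, _ = sample_nuts(lp, 3, n_chains=1, n_warmup=100, n_draws=100,
                            seed=7)
        d2, _ = sample_nuts(lp, 3, n_chains=1, n_warmup=100, n_draws=100,
                            seed=7)
        assert np.array_equal(d1, d2)

    def test_dense_mass_handles_linear_ridge(self):
        n = 40
        A = np.eye(n)
        A[0, 1:] = 0.9 / np.sqrt(n - 1)
        cov = A @ A.T + 0.01 * np.eye(n)
        prec = np.linalg.inv(cov)

        def lp(x):
            return -0.5 * x @ prec @ x, -prec @ x

        draws, st = sample_nuts(lp, n, n_chains=1, n_warmup=400, n_draws=300,
                                seed=0)
        # after dense adaptation trajectories should be short
        assert np.median(st[0].tree_depth) <= 6
        flat = draws.reshape(-1, n)
        assert abs(flat[:, 0].std() - np.sqrt(cov[0, 0])) < 0.3


class TestLKJ:
    def test_construction_yields_valid_correlation(self):
        rng = np.random.default_rng(0)
        for d in (2, 3, 5, 7):
            m = d * (d - 1) // 2
            y = rng.standard_normal(m)
            L, _ = lkj_cholesky(ad.Var(y), d)
            R = L.value @ L.value.T
            assert np.allclose(np.diag(R), 1.0)
            assert np.all(np.linalg.eigvalsh(R) > 0)

    def test_cpc_betas_reproduce_lkj_marginal(self):
        # sampling the CPCs from their implied Beta laws and composing the
        # lag-2 correlation must reproduce the analytic LKJ marginal
        eta, n = 2.0, 100_000
        rng = np.random.default_rng(1)
        p10 = 2 * rng.beta(eta + 0.5, eta + 0.5, n) - 1
        p20 = 2 * rng.beta(eta + 0.5, eta + 0.5, n) - 1
        p21 = 2 * rng.beta(eta, eta, n) - 1
        r21 = p10 * p20 + p21 * np.sqrt((1 - p10 ** 2) * (1 - p20 ** 2))
        ks = stats.kstest((r21 + 1) / 2, "beta", args=(eta + 0.5, eta + 0.5))
        assert ks.pvalue > 0.001

    def test_prior_exponents_match_construction(self):
        _, beta, _ = _cpc_matrices(4, 2.0)
        # column j exponent: eta + (d - 2 - j)/2
        assert beta[1, 0] == beta[2, 0] == beta[3, 0] == 3.0
        assert beta[2, 1] == beta[3, 1] == 2.5
        assert beta[3, 2] == 2.0

    def test_folded_halfnormal_prior_law(self):
        # NUTS samples of sigma = |u| under the folded prior match the
        # half-normal(2) law
        def lp(x):
            v, g = halfnormal_sd(ad.Var(x), 2.0)
            return float((-0.125 * x @ x)), -0.25 * x

        draws, _ = sample_nuts(lp, 1, n_chains=1, n_warmup=300, n_draws=4000,
                               seed=5)
        sig = np.abs(draws.ravel())
        ks = stats.kstest(sig, "halfnorm", args=(0, 2.0))
        assert ks.pvalue > 0.001


class TestSamplerAgreement:
    """The three regression samplers target one posterior; their summaries
    must agree on a shared small dataset."""

    @pytest.fixture(scope="class")
    def posteriors(self):
        from hexdiv.regression import (ModelSpec, fit_model,
                                       simulate_regression_dataset)
        from hexdiv._gibbs import fit_model_gibbs
        from hexdiv._marginal import fit_model_marginal

        rows, _ = simulate_regression_dataset(
            n_cells=12, n_features=4, n_areas=2, seed=21,
            beta={"r": 0.2, "t": -0.1, "f": 0.4}, predictors=("r", "t", "f"),
            tau_feat=np.full(4, 0.2), tau_area=np.full(4, 0.15))
        spec = ModelSpec("m4", use_spline=False)
        fg = fit_model_gibbs(spec, rows, n_warmup=400, n_draws=4000, seed=1,
                             check_convergence=False, diagnostics=False)
        fn = fit_model(spec, rows, n_chains=1, n_warmup=350, n_draws=350,
                       seed=5, check_convergence=False, diagnostics=False)
        fm = fit_model_marginal(spec, rows, n_chains=1, n_warmup=300,
                                n_draws=350, seed=4, check_convergence=False,
                                diagnostics=False)
        return fg, fn, fm

    @pytest.mark.parametrize("name,atol",
                             [("beta_f", 0.12), ("beta_r", 0.12),
                              ("sigma", 0.03), ("alpha", 0.12)])
    def test_posterior_means_agree(self, posteriors, name, atol):
        means = [f.posterior.stacked(name).mean() for f in posteriors]
        assert max(means) - min(means) < atol

    @pytest.mark.parametrize("name", ["beta_f", "sigma"])
    def test_posterior_sds_agree(self, posteriors, name):
        sds = [f.posterior.stacked(name).std() for f in posteriors]
        assert max(sds) < 1.8 * min(sds) + 0.02


def test_fit_sweep_warm_start_matches_single_fits():
    """The warm-started replicate sweep returns fits whose posteriors are
    plausible for their own data (smoke check on two replicates)."""
    from hexdiv.regression import ModelSpec, simulate_regression_dataset
    from hexdiv._marginal import fit_sweep

    rows_list = []
    for rep in range(2):
        rows, _ = simulate_regression_dataset(
            n_cells=8, n_features=3, n_areas=2, seed=400 + rep,
            structure_seed=9, beta={"r": 0.3, "t": 0.0},
            predictors=("r", "t"),
            tau_feat=np.full(3, 0.15), tau_area=np.full(3, 0.1))
        rows_list.append(rows)
    fits = fit_sweep(ModelSpec("m1", use_spline=False), rows_list,
                     n_warmup=150, n_warmup_rest=40, n_draws=120, seed=3)
    assert len(fits) == 2
    for f in fits:
        br = f.posterior.stacked("beta_r")
        assert np.isfinite(br).all()
        assert abs(br.mean() - 0.3) < 1.0
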