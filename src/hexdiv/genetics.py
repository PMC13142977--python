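"""Individual Wright's F from SNP genotypes and hierarchical cell smoothing.

Wright's inbreeding coefficient per individual is the excess of observed over
Hardy–Weinberg-expected homozygous genotypes,

    F = (H_O - H_E) / (N_NM - H_E),

with H_E summed over the individual's non-missing SNPs as 1 - 2 p q c_j.  The
correction factor c_j defaults to the small-sample form N_j / (N_j - 1)
(N_j = non-missing individuals at SNP j, as in the standard PLINK-style
estimator); c_j = 1 gives the uncorrected Hardy–Weinberg expectation.

Cell-level F is then obtained from a hierarchical Gaussian model with random
intercepts for geohistorical area, grid cell and population plus a
tensor-product spatial smooth, and finally z-scored across cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._bayes import Posterior
from .splines import TensorSpline


# ---------------------------------------------------------------------------
# Wright's F per individual
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Pooled alternate-allele frequencies from a {0,1,2,NaN} matrix."""
    g = np.asarray(genotypes, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nansum(g, axis=0) / (2.0 * np.sum(~np.isnan(g), axis=0))


def compute_individual_F(genotypes, individual_ids=None, allele_freqs=None,
                         small_sample_correction: bool = True) -> pd.DataFrame:
    """Per-individual Wright's F from a genotype matrix.

    Parameters
    ----------
    genotypes:
        (n_individuals, n_snps) array or DataFrame of {0, 1, 2} alternate
        allele counts with NaN for missing calls.
    allele_freqs:
        optional per-SNP frequencies; estimated from the pooled sample when
        omitted.  Monomorphic SNPs (freq 0 or 1) are excluded.
    small_sample_correction:
        multiply 2pq by N_j/(N_j - 1); set False for the plain
        Hardy–Weinberg expectation.

    Returns a DataFrame with columns individual_id, h_o, h_e, n_nm, f;
    individuals with a degenerate denominator get f = NaN.
    """
    if isinstance(genotypes, pd.DataFrame):
        if individual_ids is None:
            individual_ids = genotypes.index.to_numpy()
        genotypes = genotypes.to_numpy(dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    if individual_ids is None:
        individual_ids = np.array([f"ind{i}" for i in range(g.shape[0])])
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("genotypes must be 0, 1, 2 or missing")

    nonmiss = ~np.isnan(g)
    n_j = nonmiss.sum(axis=0)
    p = np.asarray(allele_freqs, dtype=float) if allele_freqs is not None \
        else allele_frequencies(g)
    include = (p > 0.0) & (p < 1.0) & (n_j > (1 if small_sample_correction else 0))
    q = 1.0 - p
    c = np.ones_like(p)
    if small_sample_correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(n_j > 1, n_j / np.maximum(n_j - 1.0, 1e-12), 1.0)
    exp_hom_j = np.where(include, 1.0 - 2.0 * p * q * c, 0.0)

    obs_hom = np.where(nonmiss & include[None, :],
                       (g == 0.0) | (g == 2.0), False)
    nm = (nonmiss & include[None, :])
    h_o = obs_hom.sum(axis=1).astype(float)
    n_nm = nm.sum(axis=1).astype(float)
    h_e = (nm * exp_hom_j[None, :]).sum(axis=1)
    denom = n_nm - h_e
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (h_o - h_e) / denom, np.nan)
    return pd.DataFrame({"individual_id": individual_ids, "h_o": h_o,
                         "h_e": h_e, "n_nm": n_nm, "f": f})


# ---------------------------------------------------------------------------
# hierarchical cell-level smoothing
# ---------------------------------------------------------------------------

def fit_F_model(f_table: pd.DataFrame, grid, *, n_spline_basis: int = 5,
                n_chains: int = 4, n_warmup: int = 500, n_draws: int = 500,
                seed: int = 0, check_convergence: bool = True,
              diagnostics: bool = True):
    """Smooth individual F into per-cell posterior estimates.

    `f_table` needs columns f, population, area and either cell_id or
    lon/lat (points are assigned to grid cells when cell_id is absent).
    Returns (cell_estimates DataFrame, Posterior); the cell estimate is the
    posterior of the cell-level expected F (intercept + area + cell + smooth,
    population effects marginalised at zero).
    """
    tab = f_table.dropna(subset=["f"]).copy()
    if "cell_id" not in tab.columns:
        tab["cell_id"] = grid.assign_points(tab["lon"].to_numpy(),
                                            tab["lat"].to_numpy())
    y = tab["f"].to_numpy(dtype=float)
    cell_idx, cell_levels = pd.factorize(tab["cell_id"], sort=True)
    area_idx, area_levels = pd.factorize(tab["area"], sort=True)
    pop_idx, pop_levels = pd.factorize(tab["population"], sort=True)
    pos = grid.cell_index(cell_levels)
    cx = np.array([grid.cells[p].centroid_xy[0] for p in pos])
    cy = np.array([grid.cells[p].centroid_xy[1] for p in pos])
    spline = TensorSpline.fit_domain(cx, cy, n_basis=n_spline_basis)
    basis_cells = spline.basis(cx, cy)
    basis_rows = basis_cells[cell_idx]

    area_of_cell = np.empty(len(cell_levels), dtype=int)
    for c in range(len(cell_levels)):
        vals, counts = np.unique(area_idx[cell_idx == c], return_counts=True)
        area_of_cell[c] = vals[np.argmax(counts)]

    # Collapsed inference: the model is linear-Gaussian given the five scale
    # parameters (area/cell/population/spline SDs and residual sigma), so the
    # coefficients are integrated out analytically and NUTS runs on the
    # 5-dimensional scale posterior; coefficients are recovered afterwards by
    # exact conjugate draws.  Same posterior as sampling everything jointly.
    n = len(y)
    n_area, n_cell, n_pop = len(area_levels), len(cell_levels), len(pop_levels)
    kk = spline.n_coef
    p = 1 + n_area + n_cell + n_pop + kk
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    ar = np.arange(n)
    X[ar, 1 + area_idx] = 1.0
    X[ar, 1 + n_area + cell_idx] = 1.0
    X[ar, 1 + n_area + n_cell + pop_idx] = 1.0
    X[:, 1 + n_area + n_cell + n_pop:] = basis_rows
    C = X.T @ X
    b0 = X.T @ y
    yy = float(y @ y)
    block_slices = {
        "area": slice(1, 1 + n_area),
        "cell": slice(1 + n_area, 1 + n_area + n_cell),
        "pop": slice(1 + n_area + n_cell, 1 + n_area + n_cell + n_pop),
        "spline": slice(1 + n_area + n_cell + n_pop, p),
    }
    prior_var_alpha = 4.0
    hyper_names = ["u_area", "u_cell", "u_pop", "u_spline", "u_sigma"]

    def _lambda_inv(scales):
        lam_inv = np.empty(p)
        lam_inv[0] = 1.0 / prior_var_alpha
        logdet = np.log(prior_var_alpha)
        for name, s in zip(("area", "cell", "pop", "spline"), scales):
            sl = block_slices[name]
            lam_inv[sl] = 1.0 / s ** 2
            logdet += 2.0 * (sl.stop - sl.start) * np.log(s)
        return lam_inv, logdet

    from scipy.linalg import cho_factor, cho_solve

    def logp_grad(u):
        scales = np.abs(u[:4]) + 1e-8
        sigma = abs(u[4]) + 1e-8
        s2 = sigma ** 2
        lam_inv, logdet_lam = _lambda_inv(scales)
        A = C / s2
        A[np.diag_indices(p)] += lam_inv
        cf = cho_factor(A, lower=True, check_finite=False)
        logdet_A = 2.0 * np.sum(np.log(np.diag(cf[0])))
        b = b0 / s2
        Ainv_b = cho_solve(cf, b, check_finite=False)
        quad = yy / s2 - float(b @ Ainv_b)
        loglik = -0.5 * (quad + n * np.log(s2) + logdet_lam + logdet_A
                         + n * np.log(2 * np.pi))
        logprior = -0.125 * float(u @ u)     # half-normal(2) on each scale
        # gradients via M = X'GX and tr(K^-1)
        V = cho_solve(cf, np.eye(p), check_finite=False)
        CV = C @ V
        M = (C - CV @ C / s2) / s2
        u_vec = b0 / s2 - (C @ Ainv_b) / s2      # X' alpha
        M = M - np.outer(u_vec, u_vec)
        grad = np.empty(5)
        for i, name in enumerate(("area", "cell", "pop", "spline")):
            sl = block_slices[name]
            tr = float(np.trace(M[sl, sl]))
            su = 1.0 if u[i] == 0 else np.sign(u[i])
            grad[i] = -tr * scales[i] * su - 0.25 * u[i]
        # residual sigma: tr(K^-1) = n/s2 - tr(V C)/s2^2
        tr_kinv = n / s2 - float(np.trace(CV)) / s2 ** 2
        alpha_vec_sq = (yy - 2 * float(b0 @ Ainv_b)
                        + float(Ainv_b @ (C @ Ainv_b))) / s2 ** 2
        su = 1.0 if u[4] == 0 else np.sign(u[4])
        grad[4] = -0.5 * (tr_kinv - alpha_vec_sq) * 2.0 * sigma * su \
            - 0.25 * u[4]
        return loglik + logprior, grad

    from ._nuts import sample_nuts
    raw, stats = sample_nuts(logp_grad, 5, n_chains=n_chains,
                             n_warmup=n_warmup, n_draws=n_draws, seed=seed)

    # conjugate coefficient recovery and cell-level expected F
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    nch, nd = raw.shape[0], raw.shape[1]
    named = {"sigma": np.abs(raw[..., 4]) + 1e-8,
             "sigma_area": np.abs(raw[..., 0]) + 1e-8,
             "sigma_cell": np.abs(raw[..., 1]) + 1e-8,
             "sigma_pop": np.abs(raw[..., 2]) + 1e-8,
             "sigma_spline": np.abs(raw[..., 3]) + 1e-8}
    mu_cell = np.empty((nch, nd, n_cell))
    alpha_dr = np.empty((nch, nd))
    for c in range(nch):
        for t in range(nd):
            u = raw[c, t]
            scales = np.abs(u[:4]) + 1e-8
            s2 = (abs(u[4]) + 1e-8) ** 2
            lam_inv, _ = _lambda_inv(scales)
            A = C / s2
            A[np.diag_indices(p)] += lam_inv
            cf = cho_factor(A, lower=True, check_finite=False)
            mean = cho_solve(cf, b0 / s2, check_finite=False)
            from scipy.linalg import solve_triangular
            theta = mean + solve_triangular(cf[0], rng.standard_normal(p),
                                            lower=True, trans="T",
                                            check_finite=False)
            alpha_dr[c, t] = theta[0]
            a_area = theta[block_slices["area"]]
            a_cell = theta[block_slices["cell"]]
            b_spl = theta[block_slices["spline"]]
            mu_cell[c, t] = (theta[0] + a_area[area_of_cell] + a_cell
                             + basis_cells @ b_spl)
    named["alpha"] = alpha_dr
    named["mu_cell"] = mu_cell

    rhat, ess = {}, {}
    if diagnostics:
        from ._bayes import _split_rhat_ess
        for kname, v in named.items():
            r, e = _split_rhat_ess(v)
            rhat[kname] = r
            ess[kname] = e
    post = Posterior(draws=named, rhat=rhat, ess_bulk=ess,
                     n_divergent=sum(s.n_divergent for s in stats),
                     layout=None, raw=raw, sampler_stats=stats)
    if check_convergence and diagnostics:
        post.check_convergence()
    mu = post.stacked("mu_cell")
    est = pd.DataFrame({
        "cell_id": cell_levels,
        "area": np.asarray(area_levels)[area_of_cell],
        "mean_f": mu.mean(axis=0),
        "sd_f": mu.std(axis=0, ddof=1),
        "n_individuals": np.bincount(cell_idx),
    })
    return est, post


def scale_F(estimates: pd.DataFrame) -> pd.DataFrame:
    """z-score posterior mean F across cells; SDs share the scale factor."""
    if len(estimates) < 2:
        raise ValueError("need at least two cells to scale")
    mean = estimates["mean_f"].mean()
    scale = estimates["mean_f"].std(ddof=1)
    if scale < 1e-12:
        raise ValueError("zero variance in cell means; cannot scale")
    out = estimates.copy()
    out["scaled_f"] = (out["mean_f"] - mean) / scale
    out["scaled_sd_f"] = out["sd_f"] / scale
    return out
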