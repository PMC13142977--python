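"""Measurement-error hierarchical regression of logit entropy on diversity
predictors, with the m1–m8 additive model ladder and PSIS-LOO comparison.

The response is the posterior mean logit normalized entropy per feature and
cell, observed with known SD; the total observation SD is
sqrt(sd(logit Hn)^2 + sigma^2) with a fitted residual sigma.  Fixed effects
come from the ladder {richness R, taxonomic diversity T, environment P1/P2,
population density D, scaled Wright's F}; every included fixed effect gets
correlated varying slopes by feature and by area (LKJ(2) priors on the
correlation matrices), intercepts additionally vary by grid cell, and a
tensor-product spline smooths over projected cell coordinates.  When F is
included it enters as a latent cell-level predictor with a Normal
measurement model around its estimated value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _ad as ad
from ._bayes import (ParamLayout, Posterior, correlated_effects,
                     halfnormal_sd, iid_normal_block, lkj_cholesky,
                     normal_logpdf_sum, run_mcmc)
from .splines import TensorSpline

PREDICTORS = ("r", "t", "p1", "p2", "d", "f")

MODEL_LADDER = {
    "m1": ("r", "t"),
    "m2": ("r", "t", "p1", "p2"),
    "m3": ("r", "t", "d"),
    "m4": ("r", "t", "f"),
    "m5": ("r", "t", "p1", "p2", "d"),
    "m6": ("r", "t", "p1", "p2", "f"),
    "m7": ("r", "t", "d", "f"),
    "m8": ("r", "t", "p1", "p2", "d", "f"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the model ladder."""

    name: str
    predictors: tuple = None
    n_spline_basis: int = 5
    use_spline: bool = True
    prior_sd: float = 2.0

    def __post_init__(self):
        if self.predictors is None:
            if self.name not in MODEL_LADDER:
                raise ValueError(f"unknown model {self.name!r}")
            object.__setattr__(self, "predictors", MODEL_LADDER[self.name])
        unknown = set(self.predictors) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors {unknown}")


# ---------------------------------------------------------------------------
# taxonomic diversity surrogate
# ---------------------------------------------------------------------------

def taxonomic_diversity(taxonomy_paths) -> float:
    """Effective-branch taxonomic diversity of one cell's languages.

    Surrogate index: over taxonomy levels (family, branch, ..., language),
    the mean of the effective number of distinct nodes — exp of the Shannon
    entropy of node frequencies — at each level.  One language scores 1;
    k languages from k single-language families score k; adding a language
    from a new family raises the index more than adding a sister dialect
    inside an existing branch.
    """
    paths = [str(p).split("/") for p in taxonomy_paths]
    if len(paths) == 0:
        raise ValueError("taxonomic diversity undefined for an empty cell")
    depth = max(len(p) for p in paths)
    effs = []
    for level in range(1, depth + 1):
        nodes = ["/".join(p[:min(level, len(p))]) for p in paths]
        _, counts = np.unique(nodes, return_counts=True)
        freqs = counts / counts.sum()
        h = -(freqs * np.log(freqs)).sum()
        effs.append(np.exp(h))
    return float(np.mean(effs))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(entropy_df: pd.DataFrame, f_cells: pd.DataFrame,
                  covariates: pd.DataFrame, grid) -> pd.DataFrame:
    """Join entropy summaries, cell F estimates and covariates into rows.

    Keeps cells where linguistic and genetic data are both available; one row
    per (feature, cell).  Predictors are centred and scaled over the unique
    included cells (not over rows) so feature coverage does not weight them;
    F is z-scored the same way with its SD divided by the same factor.
    """
    cells = (set(entropy_df["cell_id"]) & set(f_cells["cell_id"])
             & set(covariates["cell_id"]))
    if not cells:
        raise ValueError("no cells hold both linguistic and genetic data")
    ent = entropy_df[entropy_df["cell_id"].isin(cells)].copy()
    cov = covariates.set_index("cell_id").loc[sorted(cells)]
    fc = f_cells.set_index("cell_id").loc[sorted(cells)]

    def cscale(x):
        x = np.asarray(x, dtype=float)
        s = x.std(ddof=1)
        return (x - x.mean()) / (s if s > 1e-12 else 1.0)

    pred = pd.DataFrame(index=cov.index)
    pred["r"] = cscale(cov["log_richness"])
    pred["t"] = cscale(np.log(np.maximum(cov["taxonomic_diversity"], 1e-12)))
    pred["p1"] = cscale(cov["pc1"])
    pred["p2"] = cscale(cov["pc2"])
    pred["d"] = cscale(cov["log_density"])
    f_scale = fc["mean_f"].std(ddof=1)
    f_scale = f_scale if f_scale > 1e-12 else 1.0
    pred["f_obs"] = (fc["mean_f"] - fc["mean_f"].mean()) / f_scale
    pred["f_sd"] = fc["sd_f"] / f_scale
    pred["area"] = fc["area"]
    pos = grid.cell_index(pred.index.to_numpy())
    pred["x"] = [grid.cells[p].centroid_xy[0] for p in pos]
    pred["y"] = [grid.cells[p].centroid_xy[1] for p in pos]

    rows = ent.merge(pred, left_on="cell_id", right_index=True, how="inner")
    rows = rows.rename(columns={"mean_logit_hn": "y_obs",
                                "sd_logit_hn": "y_sd"})
    return rows.sort_values(["feature_id", "cell_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    spec: ModelSpec
    posterior: Posterior
    feature_levels: np.ndarray
    area_levels: np.ndarray
    cell_levels: np.ndarray
    log_lik: np.ndarray      # (chain, draw, n_rows)
    n_rows: int
    data_fingerprint: float


def fit_model(spec: ModelSpec, rows: pd.DataFrame, *, n_chains: int = 2,
              n_warmup: int = 300, n_draws: int = 300, seed: int = 0,
              target_accept: float = 0.8, max_treedepth: int = 10,
              check_convergence: bool = True,
              diagnostics: bool = True, dense_mass=None) -> RegressionFit:
    """Fit one ladder model to regression rows.

    Rows need columns feature_id, cell_id, area, y_obs, y_sd, x, y, the
    included predictors, and f_obs/f_sd when F is included.
    """
    feat_idx, feat_levels = pd.factorize(rows["feature_id"], sort=True)
    area_idx, area_levels = pd.factorize(rows["area"], sort=True)
    cell_idx, cell_levels = pd.factorize(rows["cell_id"], sort=True)
    if len(feat_levels) < 2 or len(area_levels) < 2:
        raise ValueError("need at least 2 features and 2 areas for the "
                         "correlated varying effects")
    y = rows["y_obs"].to_numpy(dtype=float)
    y_sd = rows["y_sd"].to_numpy(dtype=float)
    n = len(rows)
    preds = list(spec.predictors)
    k = len(preds)
    d_block = 1 + k
    use_f = "f" in preds
    x_cols = {p: rows[p].to_numpy(dtype=float) for p in preds if p != "f"}
    if use_f:
        cell_first = pd.DataFrame(
            {"cell": cell_idx, "fo": rows["f_obs"], "fs": rows["f_sd"]}
        ).groupby("cell").first()
        f_obs_cell = cell_first["fo"].to_numpy(dtype=float)
        f_sd_cell = cell_first["fs"].to_numpy(dtype=float)

    spline = None
    basis_cells = None
    if spec.use_spline:
        cf = pd.DataFrame({"cell": cell_idx, "x": rows["x"], "y": rows["y"]}
                          ).groupby("cell").first()
        spline = TensorSpline.fit_domain(cf["x"].to_numpy(),
                                         cf["y"].to_numpy(),
                                         n_basis=spec.n_spline_basis)
        basis_cells = spline.basis(cf["x"].to_numpy(), cf["y"].to_numpy())

    nf, na, nc = len(feat_levels), len(area_levels), len(cell_levels)
    m_cpc = d_block * (d_block - 1) // 2
    layout = ParamLayout()
    layout.add("alpha")
    layout.add("beta", (k,))
    layout.add("z_feat", (nf, d_block))
    layout.add("z_area", (na, d_block))
    layout.add("u_feat", (d_block,))
    layout.add("u_area", (d_block,))
    layout.add("y_feat", (m_cpc,))
    layout.add("y_area", (m_cpc,))
    layout.add("z_cell", (nc,))
    layout.add("u_cell")
    layout.add("u_sigma")
    if use_f:
        layout.add("z_flat", (nc,))
    if spec.use_spline:
        layout.add("b_spline", (spline.n_coef,))
        layout.add("u_spline")

    prior_sd = spec.prior_sd
    y_sd2 = y_sd ** 2
    # embed beta (k,) into the slope-block layout (d,) with a leading zero
    beta_embed = np.zeros((d_block, k))
    beta_embed[1:, :] = np.eye(k)
    ones_col = np.ones(n)
    x_design = None
    if not use_f:
        # fully constant design: (n, d) with leading ones column
        x_design = np.column_stack([ones_col]
                                   + [x_cols[p] for p in preds])
    else:
        f_col_pos = preds.index("f") + 1

    def logp(leaf):
        alpha = layout.var(leaf, "alpha")
        beta = layout.var(leaf, "beta")
        lp = normal_logpdf_sum(alpha, sd=prior_sd) \
            + normal_logpdf_sum(beta, sd=prior_sd)
        tau_f, lp_t = halfnormal_sd(layout.var(leaf, "u_feat"), prior_sd)
        lp = lp + lp_t
        tau_a, lp_t = halfnormal_sd(layout.var(leaf, "u_area"), prior_sd)
        lp = lp + lp_t
        L_f, lp_t = lkj_cholesky(layout.var(leaf, "y_feat"), d_block, 2.0)
        lp = lp + lp_t
        L_a, lp_t = lkj_cholesky(layout.var(leaf, "y_area"), d_block, 2.0)
        lp = lp + lp_t
        eff_f, lp_t = correlated_effects(layout.var(leaf, "z_feat"), L_f,
                                         tau_f)
        lp = lp + lp_t
        eff_a, lp_t = correlated_effects(layout.var(leaf, "z_area"), L_a,
                                         tau_a)
        lp = lp + lp_t
        sd_cell, lp_t = halfnormal_sd(layout.var(leaf, "u_cell"), prior_sd)
        lp = lp + lp_t
        a_cell, lp_t = iid_normal_block(layout.var(leaf, "z_cell"), sd_cell)
        lp = lp + lp_t
        sigma, lp_t = halfnormal_sd(layout.var(leaf, "u_sigma"), prior_sd)
        lp = lp + lp_t

        # slope blocks per row: (n, d) = fixed + by-feature + by-area
        slopes = (ad.gather(eff_f, feat_idx) + ad.gather(eff_a, area_idx)
                  + (beta_embed @ beta))
        # cell-level intercept contribution (random intercept + smooth)
        cell_total = a_cell
        if spec.use_spline:
            sd_spl, lp_t = halfnormal_sd(layout.var(leaf, "u_spline"),
                                         prior_sd)
            lp = lp + lp_t
            b_raw = layout.var(leaf, "b_spline")
            lp = lp + normal_logpdf_sum(b_raw)
            cell_total = cell_total + basis_cells @ (b_raw * sd_spl)
        if use_f:
            z_flat = layout.var(leaf, "z_flat")
            lp = lp + normal_logpdf_sum(z_flat)
            f_true = z_flat * f_sd_cell + f_obs_cell
            f_rows = ad.gather(f_true, cell_idx)
            cols = [ad.Var(ones_col)]
            for j, p in enumerate(preds):
                cols.append(f_rows if p == "f" else ad.Var(x_cols[p]))
            design = ad.stack(cols, axis=1)
            eta = alpha + (slopes * design).sum(axis=1) \
                + ad.gather(cell_total, cell_idx)
        else:
            eta = alpha + (slopes * x_design).sum(axis=1) \
                + ad.gather(cell_total, cell_idx)
        si2 = sigma * sigma + y_sd2
        resid2 = (y - eta) ** 2.0
        loglik = (resid2 / si2).sum() * -0.5 - ad.log(si2).sum() * 0.5
        return lp + loglik

    def transform(lay, raw):
        out = {
            "alpha": lay.extract(raw, "alpha"),
            "sigma": np.abs(lay.extract(raw, "u_sigma")),
            "sigma_cell": np.abs(lay.extract(raw, "u_cell")),
            "tau_feat": np.abs(lay.extract(raw, "u_feat")),
            "tau_area": np.abs(lay.extract(raw, "u_area")),
        }
        beta = lay.extract(raw, "beta")
        for j, p in enumerate(preds):
            out[f"beta_{p}"] = beta[..., j]
        # reconstruct correlated effects per draw (vectorised over draws)
        eff_feat = _effects_from_draws(lay, raw, "z_feat", "y_feat", "u_feat",
                                       d_block)
        eff_area = _effects_from_draws(lay, raw, "z_area", "y_area", "u_area",
                                       d_block)
        out["eff_feat"] = eff_feat
        out["eff_area"] = eff_area
        out["a_cell"] = lay.extract(raw, "z_cell") \
            * out["sigma_cell"][..., None]
        if use_f:
            out["f_true"] = lay.extract(raw, "z_flat") * f_sd_cell \
                + f_obs_cell
        if spec.use_spline:
            out["sigma_spline"] = np.abs(lay.extract(raw, "u_spline"))
            out["b_spline"] = lay.extract(raw, "b_spline") \
                * out["sigma_spline"][..., None]
        return out

    post = run_mcmc(logp, layout, transform, n_chains=n_chains,
                    n_warmup=n_warmup, n_draws=n_draws, seed=seed,
                    target_accept=target_accept, max_treedepth=max_treedepth,
                    diagnostics=diagnostics, dense_mass=dense_mass)
    if check_convergence and diagnostics:
        post.check_convergence()

    # pointwise log likelihood for LOO (vectorised per chain)
    eta = (post.draws["alpha"][..., None]
           + post.draws["eff_feat"][..., feat_idx, 0]
           + post.draws["eff_area"][..., area_idx, 0]
           + post.draws["a_cell"][..., cell_idx])
    if spec.use_spline:
        spl_cells = np.einsum("ck,...k->...c", basis_cells,
                              post.draws["b_spline"])
        eta = eta + spl_cells[..., cell_idx]
    for j, p in enumerate(preds):
        slope = (post.draws[f"beta_{p}"][..., None]
                 + post.draws["eff_feat"][..., feat_idx, j + 1]
                 + post.draws["eff_area"][..., area_idx, j + 1])
        xj = post.draws["f_true"][..., cell_idx] if p == "f" \
            else x_cols[p][None, None, :]
        eta = eta + slope * xj
    si2 = post.draws["sigma"][..., None] ** 2 + y_sd2[None, None, :]
    log_lik = -0.5 * ((y - eta) ** 2 / si2 + np.log(2 * np.pi * si2))

    return RegressionFit(spec=spec, posterior=post,
                         feature_levels=np.asarray(feat_levels),
                         area_levels=np.asarray(area_levels),
                         cell_levels=np.asarray(cell_levels),
                         log_lik=log_lik, n_rows=n,
                         data_fingerprint=float(np.sum(y) + n))


def _effects_from_draws(lay, raw, z_name, y_name, u_name, d):
    """Rebuild diag(tau) L z_g per draw in numpy (mirrors the model graph)."""
    z = lay.extract(raw, z_name)                 # (..., G, d)
    yv = lay.extract(raw, y_name)                # (..., m)
    tau = np.abs(lay.extract(raw, u_name))       # (..., d)
    lead = z.shape[:-2]
    p = np.zeros(lead + (d, d))
    kk = 0
    for i in range(1, d):
        for j in range(i):
            p[..., i, j] = np.tanh(yv[..., kk])
            kk += 1
    qlog = 0.5 * np.log1p(-(p ** 2))
    c = np.cumsum(qlog, axis=-1)
    c_shift = np.zeros_like(c)
    c_shift[..., 1:] = c[..., :-1]
    L = (p + np.eye(d)) * np.exp(c_shift)
    return np.einsum("...gd,...ed->...ge", z, L) * tau[..., None, :]


# ---------------------------------------------------------------------------
# model comparison and slopes
# ---------------------------------------------------------------------------

def compare_models(fits: dict) -> pd.DataFrame:
    """PSIS-LOO comparison table (elpd, SE, Delta-elpd vs best, Pareto k).

    All fits must have been run on the identical dataset.
    """
    import arviz as az
    prints = {name: (fit.n_rows, fit.data_fingerprint)
              for name, fit in fits.items()}
    if len(set(prints.values())) != 1:
        raise ValueError(f"fits use different datasets: {prints}")
    idatas = {}
    for name, fit in fits.items():
        idatas[name] = az.from_dict(
            posterior={"alpha": fit.posterior.draws["alpha"]},
            log_likelihood={"y": fit.log_lik})
    loos = {name: az.loo(idata, pointwise=True)
            for name, idata in idatas.items()}
    best = max(loos, key=lambda k: loos[k].elpd_loo)
    rows = []
    for name, lo in loos.items():
        delta_se = 0.0
        delta = 0.0
        if name != best:
            diff = (np.asarray(loos[best].loo_i) - np.asarray(lo.loo_i))
            delta = float(diff.sum())
            delta_se = float(np.sqrt(len(diff) * diff.var(ddof=1)))
        rows.append({"model": name, "elpd_loo": float(lo.elpd_loo),
                     "se": float(lo.se), "p_loo": float(lo.p_loo),
                     "d_elpd_vs_best": delta, "d_se": delta_se,
                     "best": name == best,
                     "max_pareto_k": float(np.max(lo.pareto_k))})
    return pd.DataFrame(rows).sort_values(
        "elpd_loo", ascending=False).reset_index(drop=True)


def marginal_slopes(fit: RegressionFit, group: str = "feature",
                    predictor: str = "f") -> pd.DataFrame:
    """Per-group marginal slopes beta_p + group deviation, with HPDIs.

    Returns one row per group with posterior mean, 50/89/95% HPDIs,
    P(slope > 0) and whether the 89% interval excludes zero.
    """
    from .reporting import summarize_draws
    if predictor not in fit.spec.predictors:
        raise ValueError(f"model {fit.spec.name} does not include "
                         f"{predictor!r}")
    j = list(fit.spec.predictors).index(predictor)
    beta = fit.posterior.stacked(f"beta_{predictor}")
    if group == "feature":
        dev = fit.posterior.stacked("eff_feat")[..., j + 1]
        levels = fit.feature_levels
    elif group == "area":
        dev = fit.posterior.stacked("eff_area")[..., j + 1]
        levels = fit.area_levels
    else:
        raise ValueError("group must be 'feature' or 'area'")
    out = []
    for g, level in enumerate(levels):
        s = summarize_draws(beta + dev[:, g])
        s[group] = level
        s["excludes_zero_89"] = (s["hpdi89_lower"] > 0.0
                                 or s["hpdi89_upper"] < 0.0)
        out.append(s)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# generative model for recovery and calibration studies
# ---------------------------------------------------------------------------

def simulate_regression_dataset(*, n_cells=60, n_features=8, n_areas=4,
                                beta=None, sigma_resid=0.2, tau_feat=None,
                                tau_area=None, sigma_cell=0.2,
                                y_sd_mean=0.25, f_sd_mean=0.2, seed=0,
                                predictors=MODEL_LADDER["m8"],
                                structure_seed=None,
                                spatial_amplitude=0.0):
    """Draw rows from the regression's own generative model.

    Returns (rows DataFrame, truth dict).  Cell covariates are standard
    normal; latent F is standard normal per cell and observed with Normal
    noise of SD f_sd; varying effects follow the model's hierarchical prior
    with LKJ(2) correlations.  y_sd are per-row observation SDs (half-normal
    around y_sd_mean).
    """
    rng = np.random.default_rng(seed)
    preds = list(predictors)
    k = len(preds)
    d = 1 + k
    if beta is None:
        beta = {p: rng.normal(0, 0.3) for p in preds}
    if tau_feat is None:
        tau_feat = np.full(d, 0.2)
    if tau_area is None:
        tau_area = np.full(d, 0.15)

    def lkj_draw(dim, eta=2.0):
        p = np.zeros((dim, dim))
        for i in range(1, dim):
            for jj in range(i):
                b = eta + (dim - 2 - jj) / 2.0
                p[i, jj] = 2 * rng.beta(b, b) - 1
        qlog = 0.5 * np.log1p(-(p ** 2))
        c = np.cumsum(qlog, axis=1)
        c_shift = np.zeros_like(c)
        c_shift[:, 1:] = c[:, :-1]
        return (p + np.eye(dim)) * np.exp(c_shift)

    L_f = lkj_draw(d)
    L_a = lkj_draw(d)
    eff_feat = rng.standard_normal((n_features, d)) @ L_f.T \
        * np.asarray(tau_feat)
    eff_area = rng.standard_normal((n_areas, d)) @ L_a.T \
        * np.asarray(tau_area)

    cells = np.array([f"c{c:04d}" for c in range(n_cells)])
    # a fixed structure_seed keeps the cell-to-area map (the design
    # structure) identical across replicate datasets
    struct_rng = rng if structure_seed is None \
        else np.random.default_rng(structure_seed)
    area_of_cell = struct_rng.integers(n_areas, size=n_cells)
    # planar cell coordinates (arbitrary units) and an optional smooth
    # spatial surface added to the cell intercepts
    cell_x = struct_rng.uniform(0.0, 1000.0, n_cells)
    cell_y = struct_rng.uniform(0.0, 1000.0, n_cells)
    smooth = spatial_amplitude * (np.sin(2 * np.pi * cell_x / 1000.0)
                                  * np.cos(2 * np.pi * cell_y / 1000.0))
    cov = {p: rng.standard_normal(n_cells) for p in preds if p != "f"}
    f_true = rng.standard_normal(n_cells)
    f_sd = np.abs(rng.normal(f_sd_mean, f_sd_mean / 4, n_cells)) + 1e-3
    f_obs = f_true + f_sd * rng.standard_normal(n_cells)
    a_cell = rng.normal(0, sigma_cell, n_cells) + smooth

    rows = []
    for fi in range(n_features):
        for c in range(n_cells):
            eta = (eff_feat[fi, 0] + eff_area[area_of_cell[c], 0]
                   + a_cell[c])
            for j, p in enumerate(preds):
                xval = f_true[c] if p == "f" else cov[p][c]
                eta += (beta[p] + eff_feat[fi, j + 1]
                        + eff_area[area_of_cell[c], j + 1]) * xval
            y_sd = abs(rng.normal(y_sd_mean, y_sd_mean / 4)) + 1e-3
            y_obs = eta + np.sqrt(y_sd ** 2 + sigma_resid ** 2) \
                * rng.standard_normal()
            row = {"feature_id": f"F{fi:03d}", "cell_id": cells[c],
                   "area": f"area{area_of_cell[c]:02d}",
                   "y_obs": y_obs, "y_sd": y_sd,
                   "f_obs": f_obs[c], "f_sd": f_sd[c],
                   "x": cell_x[c], "y": cell_y[c]}
            for p in preds:
                if p != "f":
                    row[p] = cov[p][c]
            rows.append(row)
    truth = {"beta": beta, "sigma_resid": sigma_resid,
             "tau_feat": np.asarray(tau_feat),
             "tau_area": np.asarray(tau_area),
             "f_true": f_true, "eff_feat": eff_feat, "eff_area": eff_area}
    return pd.DataFrame(rows), truth
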