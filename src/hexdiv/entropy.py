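"""Per-feature hierarchical models and cell-level normalized Shannon entropy.

Each linguistic feature (binary or J-state categorical) is fitted
independently with a Bayesian hierarchical logistic / softmax model: a global
baseline, random intercepts for geohistorical area, grid cell and language
family, and a tensor-product spline smooth over projected cell-centroid
coordinates.  Posterior draws of the expected state probabilities are
aggregated into one probability vector per cell and converted into normalized
Shannon entropy

    Hn = -sum_j pi_j log(pi_j) / log(J),

whose posterior mean/SD (on the raw and logit scales) feed the downstream
measurement-error regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _ad as ad
from ._bayes import (ParamLayout, Posterior, halfnormal_sd, iid_normal_block,
                     normal_logpdf_sum, run_mcmc)
from .splines import TensorSpline

LOGIT_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# entropy arithmetic
# ---------------------------------------------------------------------------

def normalized_entropy(probs, n_states: int | None = None):
    """Normalized Shannon entropy of one simplex vector or rows of a matrix.

    0*log(0) is treated as 0; the result lies in [0, 1] with 1 for the
    uniform distribution.  `n_states` defaults to the vector length.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    j = n_states if n_states is not None else p.shape[-1]
    if j < 2:
        raise ValueError("need at least two states")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1) / np.log(j)
    return float(h) if h.ndim == 0 else h


def _logit(p):
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# model spec and fit containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureModelSpec:
    feature_id: str
    n_states: int  # 2 = Bernoulli, >2 = categorical (reference coding)
    n_spline_basis: int = 5
    prior_sd: float = 2.0

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("a feature needs at least two states")


@dataclass
class FeatureFit:
    """Posterior for one feature plus the index structures for prediction."""

    spec: FeatureModelSpec
    posterior: Posterior
    cell_levels: np.ndarray
    area_levels: np.ndarray
    family_levels: np.ndarray
    cell_of_language: np.ndarray     # index into cell_levels per language row
    spline_basis_cells: np.ndarray   # (n_cells_with_data, K)
    _area_of_language: np.ndarray = None
    _family_of_language: np.ndarray = None
    _area_of_cell: np.ndarray = None
    state_levels: np.ndarray = None


@dataclass
class CellStateProbs:
    feature_id: str
    cell_id: str
    draws: np.ndarray  # (D, J), rows on the simplex


@dataclass(frozen=True)
class EntropySummary:
    feature_id: str
    cell_id: str
    mean_hn: float
    sd_hn: float
    mean_logit_hn: float
    sd_logit_hn: float


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _feature_design(language_table: pd.DataFrame, feature_id: str, grid):
    sub = language_table[language_table[feature_id].notna()].copy()
    if len(sub) == 0:
        raise ValueError(f"feature {feature_id} has no coded languages")
    states, state_levels = pd.factorize(sub[feature_id], sort=True)
    if len(state_levels) < 2:
        raise ValueError(
            f"feature {feature_id} has a single observed state; "
            "entropy is degenerate")
    for col in ("cell_id", "area", "family"):
        if sub[col].isna().any():
            bad = sub.loc[sub[col].isna(), "language_id"].tolist()[:5]
            raise ValueError(f"unmapped languages (missing {col}): {bad}")
    cell_idx, cell_levels = pd.factorize(sub["cell_id"], sort=True)
    area_idx, area_levels = pd.factorize(sub["area"], sort=True)
    fam_idx, fam_levels = pd.factorize(sub["family"], sort=True)
    pos = grid.cell_index(cell_levels)
    cx = np.array([grid.cells[p].centroid_xy[0] for p in pos])
    cy = np.array([grid.cells[p].centroid_xy[1] for p in pos])
    return (sub, states, np.asarray(state_levels), cell_idx,
            np.asarray(cell_levels), area_idx, np.asarray(area_levels),
            fam_idx, np.asarray(fam_levels), cx, cy)


def fit_feature_model(language_table: pd.DataFrame, feature_id: str, grid, *,
                      n_spline_basis: int = 5, n_chains: int = 4,
                      n_warmup: int = 500, n_draws: int = 500, seed: int = 0,
                      check_convergence: bool = True,
              diagnostics: bool = True) -> FeatureFit:
    """Fit the hierarchical state-probability model for one feature.

    The language table must carry `language_id`, `cell_id`, `area`, `family`
    and one column per feature (NaN = missing).  Binary features use a
    Bernoulli likelihood with logit link; J>2 features a categorical
    (softmax) likelihood with the first observed state as reference.
    """
    (sub, states, state_levels, cell_idx, cell_levels, area_idx, area_levels,
     fam_idx, fam_levels, cx, cy) = _feature_design(
        language_table, feature_id, grid)

    n_states = len(state_levels)
    spec = FeatureModelSpec(feature_id=feature_id, n_states=n_states,
                            n_spline_basis=n_spline_basis)
    spline = TensorSpline.fit_domain(cx, cy, n_basis=n_spline_basis)
    basis_cells = spline.basis(cx, cy)          # (n_cells, K)
    basis_rows = basis_cells[cell_idx]          # (n_lang, K)

    n_cell, n_area, n_fam = len(cell_levels), len(area_levels), len(fam_levels)
    n_free = n_states - 1                       # reference coding
    kk = spline.n_coef

    layout = ParamLayout()
    layout.add("alpha", (n_free,))
    layout.add("z_area", (n_area, n_free))
    layout.add("z_cell", (n_cell, n_free))
    layout.add("z_family", (n_fam, n_free))
    layout.add("b_spline", (kk, n_free))
    layout.add("u_area")
    layout.add("u_cell")
    layout.add("u_family")
    layout.add("u_spline")

    prior_sd = spec.prior_sd
    onehot = np.zeros((len(sub), n_states))
    onehot[np.arange(len(sub)), states] = 1.0
    y01 = (states == 1).astype(float)  # used in the binary case

    def logp(leaf):
        alpha = layout.var(leaf, "alpha")
        sd_area, lp1 = halfnormal_sd(layout.var(leaf, "u_area"), prior_sd)
        sd_cell, lp2 = halfnormal_sd(layout.var(leaf, "u_cell"), prior_sd)
        sd_fam, lp3 = halfnormal_sd(layout.var(leaf, "u_family"), prior_sd)
        sd_spl, lp4 = halfnormal_sd(layout.var(leaf, "u_spline"), prior_sd)
        a_area, lp5 = iid_normal_block(layout.var(leaf, "z_area"), sd_area)
        a_cell, lp6 = iid_normal_block(layout.var(leaf, "z_cell"), sd_cell)
        a_fam, lp7 = iid_normal_block(layout.var(leaf, "z_family"), sd_fam)
        b_raw = layout.var(leaf, "b_spline")
        b = b_raw * sd_spl
        lp8 = normal_logpdf_sum(b_raw)
        lp_alpha = normal_logpdf_sum(alpha, sd=prior_sd)

        eta = (ad.gather(a_area, area_idx) + ad.gather(a_cell, cell_idx)
               + ad.gather(a_fam, fam_idx) + basis_rows @ b + alpha)
        if n_states == 2:
            e = eta.reshape(-1)
            loglik = (e * y01).sum() - ad.log1pexp(e).sum()
        else:
            zero = ad.Var(np.zeros(len(sub)))
            eta_full = ad.stack([zero] + _columns(eta, n_free), axis=1)
            loglik = (eta_full * onehot).sum() \
                - ad.logsumexp(eta_full, axis=1).sum()
        return (loglik + lp_alpha + lp1 + lp2 + lp3 + lp4 + lp5 + lp6 + lp7
                + lp8)

    def transform(lay, raw):
        out = {
            "alpha": lay.extract(raw, "alpha"),
            "sigma_area": np.abs(lay.extract(raw, "u_area")),
            "sigma_cell": np.abs(lay.extract(raw, "u_cell")),
            "sigma_family": np.abs(lay.extract(raw, "u_family")),
            "sigma_spline": np.abs(lay.extract(raw, "u_spline")),
        }
        out["a_area"] = lay.extract(raw, "z_area") \
            * out["sigma_area"][..., None, None]
        out["a_cell"] = lay.extract(raw, "z_cell") \
            * out["sigma_cell"][..., None, None]
        out["a_family"] = lay.extract(raw, "z_family") \
            * out["sigma_family"][..., None, None]
        out["b_spline"] = lay.extract(raw, "b_spline") \
            * out["sigma_spline"][..., None, None]
        return out

    post = run_mcmc(logp, layout, transform, n_chains=n_chains,
                    n_warmup=n_warmup, n_draws=n_draws, seed=seed,
                    diagnostics=diagnostics)
    if check_convergence and diagnostics:
        post.check_convergence()
    # area of each cell (mode of member languages; in the generator a cell
    # always lies in one area)
    area_of_cell = np.empty(n_cell, dtype=int)
    for c in range(n_cell):
        vals, counts = np.unique(area_idx[cell_idx == c], return_counts=True)
        area_of_cell[c] = vals[np.argmax(counts)]
    return FeatureFit(spec=spec, posterior=post, cell_levels=cell_levels,
                      area_levels=area_levels, family_levels=fam_levels,
                      cell_of_language=cell_idx,
                      spline_basis_cells=basis_cells,
                      _area_of_language=area_idx,
                      _family_of_language=fam_idx,
                      _area_of_cell=area_of_cell,
                      state_levels=state_levels)


def _columns(mat: ad.Var, n: int):
    """Columns of a 2-D Var as 1-D Vars (constant selector matmuls)."""
    cols = []
    for j in range(n):
        e = np.zeros((mat.shape[1],))
        e[j] = 1.0
        cols.append(mat @ e)
    return cols


# ---------------------------------------------------------------------------
# posterior state probabilities and entropy summaries
# ---------------------------------------------------------------------------

def _language_probs(fit: FeatureFit) -> np.ndarray:
    """Expected state probabilities per draw and language: (D, n_lang, J)."""
    post = fit.posterior
    alpha = post.stacked("alpha")                      # (D, J-1)
    a_area = post.stacked("a_area")                    # (D, A, J-1)
    a_cell = post.stacked("a_cell")
    a_fam = post.stacked("a_family")
    b = post.stacked("b_spline")                       # (D, K, J-1)
    cell_idx = fit.cell_of_language
    # area/family index per language recoverable from cell? store directly:
    area_idx = fit._area_of_language
    fam_idx = fit._family_of_language
    basis_rows = fit.spline_basis_cells[cell_idx]      # (n, K)
    eta = (alpha[:, None, :] + a_area[:, area_idx, :] + a_cell[:, cell_idx, :]
           + a_fam[:, fam_idx, :]
           + np.einsum("nk,dkj->dnj", basis_rows, b))
    d, n, _ = eta.shape
    eta_full = np.concatenate([np.zeros((d, n, 1)), eta], axis=2)
    eta_full -= eta_full.max(axis=2, keepdims=True)
    ex = np.exp(eta_full)
    return ex / ex.sum(axis=2, keepdims=True)


def cell_state_probabilities(fit: FeatureFit, *,
                             aggregation: str = "language_mean"
                             ) -> list[CellStateProbs]:
    """Per-cell posterior draws of the feature's state probabilities.

    aggregation="language_mean" (default): per posterior draw, the cell
    probability vector is the unweighted mean of the expected state
    probabilities of the coded languages assigned to the cell.
    aggregation="cell_effect": probabilities are evaluated directly from the
    cell-level linear predictor (family effect marginalised at zero).
    """
    post = fit.posterior
    n_free = fit.spec.n_states - 1
    if aggregation == "language_mean":
        probs = _language_probs(fit)                   # (D, n_lang, J)
        out = []
        for c, cid in enumerate(fit.cell_levels):
            members = np.nonzero(fit.cell_of_language == c)[0]
            out.append(CellStateProbs(
                feature_id=fit.spec.feature_id, cell_id=str(cid),
                draws=probs[:, members, :].mean(axis=1)))
        return out
    if aggregation == "cell_effect":
        alpha = post.stacked("alpha")
        a_area = post.stacked("a_area")
        a_cell = post.stacked("a_cell")
        b = post.stacked("b_spline")
        area_of_cell = fit._area_of_cell
        eta = (alpha[:, None, :] + a_area[:, area_of_cell, :] + a_cell
               + np.einsum("ck,dkj->dcj", fit.spline_basis_cells, b))
        d, n, _ = eta.shape
        eta_full = np.concatenate([np.zeros((d, n, 1)), eta], axis=2)
        eta_full -= eta_full.max(axis=2, keepdims=True)
        ex = np.exp(eta_full)
        probs = ex / ex.sum(axis=2, keepdims=True)
        return [CellStateProbs(feature_id=fit.spec.feature_id,
                               cell_id=str(cid), draws=probs[:, c, :])
                for c, cid in enumerate(fit.cell_levels)]
    raise ValueError(f"unknown aggregation {aggregation!r}")


def summarize_entropy(cell_probs: CellStateProbs) -> EntropySummary:
    """Posterior mean/SD of Hn and logit(Hn) over the stored draws.

    Hn is clamped to [1e-6, 1 - 1e-6] before the logit to keep degenerate
    cells finite.
    """
    draws = np.asarray(cell_probs.draws, dtype=float)
    if draws.shape[0] < 2:
        raise ValueError("need at least two draws")
    hn = normalized_entropy(draws)
    hn_c = np.clip(hn, LOGIT_CLAMP, 1.0 - LOGIT_CLAMP)
    lg = _logit(hn_c)
    return EntropySummary(
        feature_id=cell_probs.feature_id, cell_id=cell_probs.cell_id,
        mean_hn=float(hn.mean()), sd_hn=float(hn.std(ddof=1)),
        mean_logit_hn=float(lg.mean()), sd_logit_hn=float(lg.std(ddof=1)))


def entropy_summaries(language_table: pd.DataFrame, feature_ids, grid, *,
                      aggregation: str = "language_mean", seed: int = 0,
                      n_chains: int = 4, n_warmup: int = 500,
                      n_draws: int = 500, n_spline_basis: int = 5,
                      check_convergence: bool = True,
              diagnostics: bool = True) -> pd.DataFrame:
    """Fit every feature and return one tidy entropy-summary table."""
    rows = []
    for k, fid in enumerate(feature_ids):
        fit = fit_feature_model(language_table, fid, grid, seed=seed + k,
                                n_chains=n_chains, n_warmup=n_warmup,
                                n_draws=n_draws, n_spline_basis=n_spline_basis,
                                check_convergence=check_convergence)
        for cp in cell_state_probabilities(fit, aggregation=aggregation):
            s = summarize_entropy(cp)
            rows.append({"feature_id": s.feature_id, "cell_id": s.cell_id,
                         "mean_hn": s.mean_hn, "sd_hn": s.sd_hn,
                         "mean_logit_hn": s.mean_logit_hn,
                         "sd_logit_hn": s.sd_logit_hn})
    return pd.DataFrame(rows)
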