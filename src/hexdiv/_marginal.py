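"""Collapsed (marginalised) inference for the measurement-error regression.

The regression is linear-Gaussian given its variance components, correlation
matrices and the latent F values: all regression coefficients (intercept,
fixed effects, correlated feature/area blocks, cell intercepts, spline
coefficients) can be integrated out in closed form,

    y ~ N(0, K),   K = D + X Lambda X',

with D the per-row observation variance (y_sd^2 + sigma^2), X the full design
including the latent-F columns, and Lambda the block-diagonal prior
covariance of the coefficients.  NUTS runs on the low-dimensional
hyperparameter posterior (scales, canonical partial correlations, residual
sigma, latent F), whose geometry is benign, and coefficients are recovered
afterwards by exact conjugate Gaussian draws.  The result is the same
posterior as the uncollapsed sampler — an inference strategy, not a
different model.

The implementation is batched over independent replicate datasets sharing
one design structure, so an entire calibration sweep (R simulated datasets,
each with its own posterior) runs as a single product-posterior NUTS chain
with block-diagonal mass adaptation and vectorised linear algebra.

Gradients use the Gaussian-marginal identities
d loglik = -0.5 tr((K^-1 - a a') dK), a = K^-1 y, with Woodbury throughout;
the LKJ/scale blocks are differentiated by a hand-rolled reverse sweep
through the canonical-partial-correlation construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._bayes import ParamLayout, Posterior, _cpc_matrices, _split_rhat_ess
from ._nuts import sample_nuts

_TAU_FLOOR = 1e-8


def _batched_cpc_chol(yv, d, il, jl):
    """Correlation Cholesky factors from CPCs; yv (R, m) -> (R, d, d)."""
    r = yv.shape[0]
    p = np.zeros((r, d, d))
    p[:, il, jl] = np.tanh(yv) * (1.0 - 1e-12)
    qlog = 0.5 * np.log1p(-(p ** 2))
    c = np.cumsum(qlog, axis=2)
    c_shift = np.zeros_like(c)
    c_shift[:, :, 1:] = c[:, :, :-1]
    return (p + np.eye(d)) * np.exp(c_shift), p


class MarginalRegression:
    """Collapsed sampler for one or more replicate datasets.

    All replicates must share the design structure (same features, areas,
    cells, predictors and row ordering); values (y, covariates, F estimates)
    differ freely.
    """

    def __init__(self, spec, rows_list, prior_sd: float = 2.0):
        self.spec = spec
        self.preds = list(spec.predictors)
        self.k = len(self.preds)
        self.d = 1 + self.k
        self.use_f = "f" in self.preds
        self.prior_sd = prior_sd
        self.R = len(rows_list)

        first = rows_list[0]
        feat_idx, self.feat_levels = pd.factorize(first["feature_id"],
                                                  sort=True)
        area_idx, self.area_levels = pd.factorize(first["area"], sort=True)
        cell_idx, self.cell_levels = pd.factorize(first["cell_id"], sort=True)
        if len(self.feat_levels) < 2 or len(self.area_levels) < 2:
            raise ValueError("need at least 2 features and 2 areas")
        for rows in rows_list[1:]:
            if not (np.array_equal(rows["feature_id"].to_numpy(),
                                   first["feature_id"].to_numpy())
                    and np.array_equal(rows["cell_id"].to_numpy(),
                                       first["cell_id"].to_numpy())
                    and np.array_equal(rows["area"].to_numpy(),
                                       first["area"].to_numpy())):
                raise ValueError("replicates must share the design structure")
        self.feat_idx, self.area_idx, self.cell_idx = (feat_idx, area_idx,
                                                       cell_idx)
        self.nf = len(self.feat_levels)
        self.na = len(self.area_levels)
        self.nc = len(self.cell_levels)
        self.n = len(first)
        n, d, k, R = self.n, self.d, self.k, self.R

        self.y = np.stack([r["y_obs"].to_numpy(dtype=float)
                           for r in rows_list])
        self.y_sd2 = np.stack([r["y_sd"].to_numpy(dtype=float)
                               for r in rows_list]) ** 2
        if self.use_f:
            fo, fs = [], []
            for rows in rows_list:
                cf = pd.DataFrame({"cell": cell_idx, "fo": rows["f_obs"],
                                   "fs": rows["f_sd"]}).groupby("cell").first()
                fo.append(cf["fo"].to_numpy(dtype=float))
                fs.append(cf["fs"].to_numpy(dtype=float))
            self.f_obs_cell = np.stack(fo)
            self.f_sd_cell = np.stack(fs)

        # spline basis over unique cells (shared or per replicate)
        self.n_spl = 0
        self.basis_cells = None
        if spec.use_spline:
            from .splines import TensorSpline
            cf = pd.DataFrame({"cell": cell_idx, "x": first["x"],
                               "y": first["y"]}).groupby("cell").first()
            spl = TensorSpline.fit_domain(cf["x"].to_numpy(),
                                          cf["y"].to_numpy(),
                                          n_basis=spec.n_spline_basis)
            self.basis_cells = spl.basis(cf["x"].to_numpy(),
                                         cf["y"].to_numpy())
            self.n_spl = self.basis_cells.shape[1]
            self.spline = spl

        # design template --------------------------------------------------
        self.sl_fixed = slice(0, 1 + k)
        self.off_feat = 1 + k
        self.off_area = self.off_feat + self.nf * d
        self.off_cell = self.off_area + self.na * d
        self.off_spl = self.off_cell + self.nc
        self.p = self.off_spl + self.n_spl

        X = np.zeros((R, n, self.p))
        X[:, :, 0] = 1.0
        ar = np.arange(n)
        self.col_feat0 = self.off_feat + feat_idx * d
        self.col_area0 = self.off_area + area_idx * d
        X[:, ar, self.col_feat0] = 1.0
        X[:, ar, self.col_area0] = 1.0
        self.x_cols = {}
        for j, pname in enumerate(self.preds):
            if pname == "f":
                continue
            xc = np.stack([rows[pname].to_numpy(dtype=float)
                           for rows in rows_list])
            self.x_cols[pname] = xc
            X[:, :, 1 + j] = xc
            X[:, ar, self.col_feat0 + 1 + j] = xc
            X[:, ar, self.col_area0 + 1 + j] = xc
        X[:, ar, self.off_cell + cell_idx] = 1.0
        if self.n_spl:
            X[:, :, self.off_spl:] = self.basis_cells[cell_idx][None]
        self.X_template = X
        if self.use_f:
            jf = self.preds.index("f")
            self.fcol_fixed = 1 + jf
            self.fcol_feat = self.col_feat0 + 1 + jf
            self.fcol_area = self.col_area0 + 1 + jf
        self.rows_arange = ar

        # per-replicate hyperparameter layout
        m = d * (d - 1) // 2
        self.m_cpc = m
        lay = ParamLayout()
        lay.add("u_sigma")
        lay.add("u_feat", (d,))
        lay.add("u_area", (d,))
        lay.add("y_feat", (m,))
        lay.add("y_area", (m,))
        lay.add("u_cell")
        if self.n_spl:
            lay.add("u_spline")
        if self.use_f:
            lay.add("z_flat", (self.nc,))
        self.layout = lay
        self.q = lay.size
        self.dim = self.q * R
        self.il, self.jl = np.tril_indices(d, -1)
        _, beta_mat, _ = _cpc_matrices(d, 2.0)
        self.beta_mat = beta_mat
        self._eye_d = np.eye(d)

    # ------------------------------------------------------------------

    def _unpack(self, xb):
        """xb: (R, q) -> dict of batched blocks."""
        lay = self.layout
        out = {}
        for name in lay.names():
            sl, shape = lay._slices[name]
            v = xb[:, sl]
            out[name] = v.reshape((self.R,) + shape) if shape else v[:, 0]
        return out

    def _build_X(self, f_true):
        X = self.X_template.copy()
        if self.use_f:
            f_rows = np.take_along_axis(
                f_true, np.broadcast_to(self.cell_idx, (self.R, self.n)),
                axis=1)
            X[:, :, self.fcol_fixed] = f_rows
            X[:, self.rows_arange, self.fcol_feat] = f_rows
            X[:, self.rows_arange, self.fcol_area] = f_rows
        return X

    def _scales(self, pars):
        d = self.d
        tau_f = np.abs(pars["u_feat"]) + _TAU_FLOOR       # (R, d)
        tau_a = np.abs(pars["u_area"]) + _TAU_FLOOR
        L_f, P_f = _batched_cpc_chol(pars["y_feat"], d, self.il, self.jl)
        L_a, P_a = _batched_cpc_chol(pars["y_area"], d, self.il, self.jl)
        A_f = tau_f[:, :, None] * L_f                      # chol of Sigma_F
        A_a = tau_a[:, :, None] * L_a
        s_cell = np.abs(pars["u_cell"]) + _TAU_FLOOR       # (R,)
        s_spl = (np.abs(pars["u_spline"]) + _TAU_FLOOR) if self.n_spl else None
        sigma = np.abs(pars["u_sigma"]) + _TAU_FLOOR
        return tau_f, tau_a, L_f, L_a, A_f, A_a, s_cell, s_spl, sigma

    def _lambda_inv_into(self, A, A_f, A_a, s_cell, s_spl):
        """Add Lambda^{-1} into A (R, p, p) in place; return log|Lambda| (R,)."""
        d = self.d
        pv = self.prior_sd ** 2
        idx = np.arange(1 + self.k)
        A[:, idx, idx] += 1.0 / pv
        logdet = np.full(self.R, (1 + self.k) * np.log(pv))
        inv_f = np.linalg.inv(A_f)
        inv_f = np.transpose(inv_f, (0, 2, 1)) @ inv_f     # Sigma_F^{-1}
        inv_a = np.linalg.inv(A_a)
        inv_a = np.transpose(inv_a, (0, 2, 1)) @ inv_a
        ld_f = 2.0 * np.sum(np.log(np.abs(
            np.diagonal(A_f, axis1=1, axis2=2))), axis=1)
        ld_a = 2.0 * np.sum(np.log(np.abs(
            np.diagonal(A_a, axis1=1, axis2=2))), axis=1)
        for g in range(self.nf):
            sl = slice(self.off_feat + g * d, self.off_feat + (g + 1) * d)
            A[:, sl, sl] += inv_f
        for g in range(self.na):
            sl = slice(self.off_area + g * d, self.off_area + (g + 1) * d)
            A[:, sl, sl] += inv_a
        logdet += self.nf * ld_f + self.na * ld_a
        idx = np.arange(self.off_cell, self.off_cell + self.nc)
        A[:, idx, idx] += (1.0 / s_cell ** 2)[:, None]
        logdet += 2.0 * self.nc * np.log(s_cell)
        if self.n_spl:
            idx = np.arange(self.off_spl, self.p)
            A[:, idx, idx] += (1.0 / s_spl ** 2)[:, None]
            logdet += 2.0 * self.n_spl * np.log(s_spl)
        return logdet

    def _lambda_mult(self, U, A_f, A_a, s_cell, s_spl):
        """U @ Lambda blockwise; U (R, n, p)."""
        d = self.d
        W = np.empty_like(U)
        W[:, :, self.sl_fixed] = U[:, :, self.sl_fixed] * self.prior_sd ** 2
        sig_f = A_f @ np.transpose(A_f, (0, 2, 1))
        sig_a = A_a @ np.transpose(A_a, (0, 2, 1))
        nfd = self.nf * d
        blk = U[:, :, self.off_feat:self.off_feat + nfd].reshape(
            self.R, -1, self.nf, d)
        W[:, :, self.off_feat:self.off_feat + nfd] = np.einsum(
            "rngd,rde->rnge", blk, sig_f).reshape(self.R, -1, nfd)
        nad = self.na * d
        blk = U[:, :, self.off_area:self.off_area + nad].reshape(
            self.R, -1, self.na, d)
        W[:, :, self.off_area:self.off_area + nad] = np.einsum(
            "rngd,rde->rnge", blk, sig_a).reshape(self.R, -1, nad)
        W[:, :, self.off_cell:self.off_cell + self.nc] = \
            U[:, :, self.off_cell:self.off_cell + self.nc] \
            * (s_cell ** 2)[:, None, None]
        if self.n_spl:
            W[:, :, self.off_spl:] = U[:, :, self.off_spl:] \
                * (s_spl ** 2)[:, None, None]
        return W

    def _lkj_block_grad(self, u, yv, adj):
        """Batched gradient of -0.5 sum(adj ∘ Sigma) + priors wrt (u, yv).

        adj: (R, d, d) symmetric adjoints; returns (gu (R, d), gy (R, m)).
        """
        d = self.d
        tau = np.abs(u) + _TAU_FLOOR
        L, P = _batched_cpc_chol(yv, d, self.il, self.jl)
        E = np.exp(np.concatenate(
            [np.zeros((self.R, d, 1)),
             np.cumsum(0.5 * np.log1p(-(P ** 2)), axis=2)[:, :, :-1]],
            axis=2))
        A = tau[:, :, None] * L
        gA = -(adj @ A)
        g_tau = (gA * L).sum(axis=2)
        gL = tau[:, :, None] * gA
        gP1 = gL * E
        gC_shift = gL * (P + self._eye_d) * E
        gC = np.zeros_like(gC_shift)
        gC[:, :, :-1] = gC_shift[:, :, 1:]
        gQ = np.flip(np.cumsum(np.flip(gC, axis=2), axis=2), axis=2)
        one_m_p2 = 1.0 - P ** 2
        gP = gP1 - gQ * P / one_m_p2 - 2.0 * self.beta_mat * P / one_m_p2
        gy = gP[:, self.il, self.jl] * (1.0 - P[:, self.il, self.jl] ** 2)
        su = np.where(u == 0, 1.0, np.sign(u))
        gu = g_tau * su - u / self.prior_sd ** 2
        return gu, gy

    # ------------------------------------------------------------------

    def logp_grad(self, x):
        xb = x.reshape(self.R, self.q)
        pars = self._unpack(xb)
        (tau_f, tau_a, L_f, L_a, A_f, A_a, s_cell, s_spl,
         sigma) = self._scales(pars)
        D = self.y_sd2 + (sigma ** 2)[:, None]
        Dinv = 1.0 / D
        f_true = None
        if self.use_f:
            f_true = self.f_obs_cell + self.f_sd_cell * pars["z_flat"]
        X = self._build_X(f_true)
        XD = X * Dinv[:, :, None]
        Xt = np.transpose(X, (0, 2, 1))
        C = np.transpose(XD, (0, 2, 1)) @ X                # (R, p, p)
        b = np.einsum("rnp,rn->rp", XD, self.y)
        A = C.copy()
        logdet_lam = self._lambda_inv_into(A, A_f, A_a, s_cell, s_spl)
        L_A = np.linalg.cholesky(A)
        logdet_A = 2.0 * np.sum(np.log(np.diagonal(L_A, axis1=1, axis2=2)),
                                axis=1)
        V = np.linalg.inv(A)
        Ainv_b = np.einsum("rpq,rq->rp", V, b)
        quad = np.einsum("rn,rn->r", self.y, Dinv * self.y) \
            - np.einsum("rp,rp->r", b, Ainv_b)
        logdet_K = np.sum(np.log(D), axis=1) + logdet_lam + logdet_A
        loglik = -0.5 * (quad + logdet_K + self.n * np.log(2 * np.pi))

        pv = self.prior_sd ** 2
        logprior = (-0.5 * pars["u_sigma"] ** 2 / pv
                    - 0.5 * pars["u_cell"] ** 2 / pv
                    - 0.5 * np.sum(pars["u_feat"] ** 2, axis=1) / pv
                    - 0.5 * np.sum(pars["u_area"] ** 2, axis=1) / pv
                    + np.sum(self.beta_mat[self.il, self.jl]
                             * np.log1p(-(np.tanh(pars["y_feat"])
                                          * (1 - 1e-12)) ** 2), axis=1)
                    + np.sum(self.beta_mat[self.il, self.jl]
                             * np.log1p(-(np.tanh(pars["y_area"])
                                          * (1 - 1e-12)) ** 2), axis=1))
        if self.n_spl:
            logprior = logprior - 0.5 * pars["u_spline"] ** 2 / pv
        if self.use_f:
            logprior = logprior - 0.5 * np.sum(pars["z_flat"] ** 2, axis=1)

        # ---- gradients -------------------------------------------------
        CV = C @ V
        M = C - CV @ C
        XVb = np.einsum("rnp,rp->rn", X, Ainv_b)
        alpha = Dinv * (self.y - XVb)
        u_vec = np.einsum("rnp,rn->rp", X, alpha)
        M = M - u_vec[:, :, None] * u_vec[:, None, :]

        grad = np.zeros((self.R, self.q))
        lay = self.layout

        XV = X @ V
        diag_XVXt = np.einsum("rnp,rnp->rn", XV, X)
        Kinv_diag = Dinv - Dinv ** 2 * diag_XVXt
        dl_dD = -0.5 * (Kinv_diag - alpha ** 2)
        su = np.where(pars["u_sigma"] == 0, 1.0, np.sign(pars["u_sigma"]))
        grad[:, lay._slices["u_sigma"][0]] = (
            np.sum(dl_dD, axis=1) * 2.0 * sigma * su
            - pars["u_sigma"] / pv)[:, None]

        d = self.d
        Mf = np.zeros((self.R, d, d))
        for g in range(self.nf):
            sl = slice(self.off_feat + g * d, self.off_feat + (g + 1) * d)
            Mf += M[:, sl, sl]
        Ma = np.zeros((self.R, d, d))
        for g in range(self.na):
            sl = slice(self.off_area + g * d, self.off_area + (g + 1) * d)
            Ma += M[:, sl, sl]
        gu, gy = self._lkj_block_grad(pars["u_feat"], pars["y_feat"],
                                      0.5 * (Mf + np.transpose(Mf, (0, 2, 1))))
        grad[:, lay._slices["u_feat"][0]] = gu
        grad[:, lay._slices["y_feat"][0]] = gy
        gu, gy = self._lkj_block_grad(pars["u_area"], pars["y_area"],
                                      0.5 * (Ma + np.transpose(Ma, (0, 2, 1))))
        grad[:, lay._slices["u_area"][0]] = gu
        grad[:, lay._slices["y_area"][0]] = gy

        idx = np.arange(self.off_cell, self.off_cell + self.nc)
        tr_cell = M[:, idx, idx].sum(axis=1)
        suc = np.where(pars["u_cell"] == 0, 1.0, np.sign(pars["u_cell"]))
        grad[:, lay._slices["u_cell"][0]] = (
            -tr_cell * s_cell * suc - pars["u_cell"] / pv)[:, None]
        if self.n_spl:
            idx = np.arange(self.off_spl, self.p)
            tr_spl = M[:, idx, idx].sum(axis=1)
            sus = np.where(pars["u_spline"] == 0, 1.0,
                           np.sign(pars["u_spline"]))
            grad[:, lay._slices["u_spline"][0]] = (
                -tr_spl * s_spl * sus - pars["u_spline"] / pv)[:, None]

        if self.use_f:
            P1 = XD - XD @ (V @ C)
            U = P1 - alpha[:, :, None] * u_vec[:, None, :]
            W = self._lambda_mult(U, A_f, A_a, s_cell, s_spl)
            wsum = (W[:, :, self.fcol_fixed]
                    + W[:, self.rows_arange, self.fcol_feat]
                    + W[:, self.rows_arange, self.fcol_area])
            grad_f = np.zeros((self.R, self.nc))
            np.add.at(grad_f.T, self.cell_idx, -wsum.T)
            grad[:, lay._slices["z_flat"][0]] = (grad_f * self.f_sd_cell
                                                 - pars["z_flat"])

        return float(np.sum(loglik) + np.sum(logprior)), grad.ravel()

    # ------------------------------------------------------------------

    def recover(self, raw, seed):
        """Conjugate coefficient draws: raw (chain, draw, dim) ->
        theta (chain, draw, R, p), sigma (chain, draw, R), f (… R, nc)."""
        n_chains, n_draws, _ = raw.shape
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        theta = np.empty((n_chains, n_draws, self.R, self.p))
        sig = np.empty((n_chains, n_draws, self.R))
        f_dr = np.empty((n_chains, n_draws, self.R, self.nc)) \
            if self.use_f else None
        for c in range(n_chains):
            for t in range(n_draws):
                xb = raw[c, t].reshape(self.R, self.q)
                pars = self._unpack(xb)
                (tau_f, tau_a, L_f, L_a, A_f, A_a, s_cell, s_spl,
                 sigma) = self._scales(pars)
                sig[c, t] = sigma
                D = self.y_sd2 + (sigma ** 2)[:, None]
                Dinv = 1.0 / D
                f_true = None
                if self.use_f:
                    f_true = self.f_obs_cell \
                        + self.f_sd_cell * pars["z_flat"]
                    f_dr[c, t] = f_true
                X = self._build_X(f_true)
                XD = X * Dinv[:, :, None]
                A = np.transpose(XD, (0, 2, 1)) @ X
                self._lambda_inv_into(A, A_f, A_a, s_cell, s_spl)
                b = np.einsum("rnp,rn->rp", XD, self.y)
                L_A = np.linalg.cholesky(A)
                mean = np.linalg.solve(A, b[..., None])[..., 0]
                xi = rng.standard_normal((self.R, self.p))
                dev = np.linalg.solve(np.transpose(L_A, (0, 2, 1)),
                                      xi[..., None])[..., 0]
                theta[c, t] = mean + dev
        return theta, sig, f_dr

    def named_draws(self, raw, theta, sig, f_dr, rep):
        """Named draws dict for replicate `rep` (shapes (chain, draw, ...))."""
        d = self.d
        th = theta[..., rep, :]
        named = {"alpha": th[..., 0], "sigma": sig[..., rep]}
        for j, p in enumerate(self.preds):
            named[f"beta_{p}"] = th[..., 1 + j]
        named["eff_feat"] = th[..., self.off_feat:self.off_feat
                               + self.nf * d].reshape(
            th.shape[:2] + (self.nf, d))
        named["eff_area"] = th[..., self.off_area:self.off_area
                               + self.na * d].reshape(
            th.shape[:2] + (self.na, d))
        named["a_cell"] = th[..., self.off_cell:self.off_cell + self.nc]
        xb = raw.reshape(raw.shape[0], raw.shape[1], self.R, self.q)
        lay = self.layout
        named["tau_feat"] = np.abs(xb[..., rep, lay._slices["u_feat"][0]])
        named["tau_area"] = np.abs(xb[..., rep, lay._slices["u_area"][0]])
        named["sigma_cell"] = np.abs(
            xb[..., rep, lay._slices["u_cell"][0]])[..., 0]
        if self.n_spl:
            named["b_spline"] = th[..., self.off_spl:]
            named["sigma_spline"] = np.abs(
                xb[..., rep, lay._slices["u_spline"][0]])[..., 0]
        if self.use_f:
            named["f_true"] = f_dr[..., rep, :]
        return named

    def log_lik(self, named, rep):
        """Pointwise log likelihood (chain, draw, n) for one replicate."""
        y = self.y[rep]
        eta = (named["alpha"][..., None]
               + named["eff_feat"][..., self.feat_idx, 0]
               + named["eff_area"][..., self.area_idx, 0]
               + named["a_cell"][..., self.cell_idx])
        if self.n_spl:
            spl_cells = np.einsum("ck,...k->...c", self.basis_cells,
                                  named["b_spline"])
            eta = eta + spl_cells[..., self.cell_idx]
        for j, p in enumerate(self.preds):
            slope = (named[f"beta_{p}"][..., None]
                     + named["eff_feat"][..., self.feat_idx, j + 1]
                     + named["eff_area"][..., self.area_idx, j + 1])
            if p == "f":
                xj = named["f_true"][..., self.cell_idx]
            else:
                xj = self.x_cols[p][rep][None, None, :]
            eta = eta + slope * xj
        si2 = named["sigma"][..., None] ** 2 + self.y_sd2[rep][None, None, :]
        return -0.5 * ((y - eta) ** 2 / si2 + np.log(2 * np.pi * si2))

    # ------------------------------------------------------------------

    def _make_fit(self, raw, stats, rep, theta, sig, f_dr, check_convergence,
                  diagnostics):
        from .regression import RegressionFit
        named = self.named_draws(raw, theta, sig, f_dr, rep)
        rhat, ess = {}, {}
        if diagnostics:
            for kname, v in named.items():
                r, e = _split_rhat_ess(v)
                rhat[kname] = r
                ess[kname] = e
        post = Posterior(
            draws=named, rhat=rhat, ess_bulk=ess,
            n_divergent=sum(s.n_divergent for s in stats),
            layout=self.layout, raw=None, sampler_stats=stats)
        if check_convergence and diagnostics:
            post.check_convergence()
        log_lik = self.log_lik(named, rep)
        return RegressionFit(
            spec=self.spec, posterior=post,
            feature_levels=np.asarray(self.feat_levels),
            area_levels=np.asarray(self.area_levels),
            cell_levels=np.asarray(self.cell_levels),
            log_lik=log_lik, n_rows=self.n,
            data_fingerprint=float(np.sum(self.y[rep]) + self.n))

    def fit(self, *, n_chains=1, n_warmup=300, n_draws=300, seed=0,
            target_accept=0.8, max_treedepth=10, check_convergence=True,
            diagnostics=True):
        """Sample the (single-dataset) posterior; returns [RegressionFit]."""
        if self.R != 1:
            raise ValueError("use fit_sweep for multiple replicates")
        raw, stats = sample_nuts(
            self.logp_grad, self.dim, n_chains=n_chains, n_warmup=n_warmup,
            n_draws=n_draws, seed=seed, target_accept=target_accept,
            max_treedepth=max_treedepth, dense_mass=self.dim <= 500)
        theta, sig, f_dr = self.recover(raw, seed)
        return [self._make_fit(raw, stats, 0, theta, sig, f_dr,
                               check_convergence, diagnostics)]


def fit_model_marginal(spec, rows, **kwargs):
    """Collapsed fit of one dataset; same posterior as `fit_model`."""
    return MarginalRegression(spec, [rows]).fit(**kwargs)[0]


def fit_sweep(spec, rows_list, *, n_warmup=250, n_warmup_rest=60,
              n_draws=150, seed=0, target_accept=0.8, max_treedepth=9,
              prior_sd=2.0):
    """Fit many replicate datasets sharing one design, cheaply.

    The first replicate gets a full adaptive warmup; subsequent replicates
    reuse its adapted mass matrix (the replicate posteriors share scale
    structure) and only re-tune the step size over a short warmup.  Each
    replicate is an independent single-chain NUTS run.  Returns a list of
    RegressionFit without convergence diagnostics — intended for calibration
    studies where per-replicate diagnostics would dominate the cost.
    """
    from ._nuts import NUTS
    fits = []
    mass = None
    step = 0.1
    seeds = np.random.SeedSequence([seed, 1009]).spawn(len(rows_list))
    for i, rows in enumerate(rows_list):
        sub = MarginalRegression(spec, [rows], prior_sd=prior_sd)
        kernel = NUTS(sub.logp_grad, sub.dim, target_accept=target_accept,
                      max_treedepth=max_treedepth,
                      dense_mass=sub.dim <= 500)
        rng = np.random.default_rng(seeds[i])
        x0 = 0.3 * rng.standard_normal(sub.dim)
        if i == 0:
            draws, st = kernel.run(x0, n_warmup, n_draws, rng)
            mass, step = st.mass, st.step_size
        else:
            draws, st = kernel.run(x0, n_warmup_rest, n_draws, rng,
                                   step_size=step, mass=mass,
                                   adapt_mass=False)
        raw = draws[None]
        theta, sig, f_dr = sub.recover(raw, int(seeds[i].generate_state(1)[0]
                                                % (2 ** 31)))
        fits.append(sub._make_fit(raw, [st], 0, theta, sig, f_dr,
                                  check_convergence=False, diagnostics=False))
    return fits
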