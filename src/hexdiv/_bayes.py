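"""Shared building blocks for the package's hierarchical Bayesian models.

All models are expressed as log posteriors over an unconstrained parameter
vector: scale parameters are sampled on the log scale with half-normal priors
(Jacobian-corrected), correlation matrices through canonical partial
correlations (CPCs) with the LKJ prior, and all hierarchical effects are
non-centred (standard-normal innovations scaled inside the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ad as ad
from ._nuts import sample_nuts

HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


class ParamLayout:
    """Named slices into a flat unconstrained parameter vector."""

    def __init__(self):
        self._slices: dict[str, tuple[slice, tuple]] = {}
        self._size = 0

    def add(self, name: str, shape=()) -> None:
        shape = tuple(shape) if not isinstance(shape, int) else (shape,)
        n = int(np.prod(shape)) if shape else 1
        self._slices[name] = (slice(self._size, self._size + n), shape)
        self._size += n

    @property
    def size(self) -> int:
        return self._size

    def var(self, leaf: ad.Var, name: str) -> ad.Var:
        sl, shape = self._slices[name]
        v = leaf.slice(sl)
        if shape:
            return v.reshape(shape)
        return v

    def extract(self, draws: np.ndarray, name: str) -> np.ndarray:
        """Slice draws of shape (..., size) down to (..., *shape)."""
        sl, shape = self._slices[name]
        out = draws[..., sl]
        if shape:
            return out.reshape(draws.shape[:-1] + shape)
        return out[..., 0]

    def names(self):
        return list(self._slices)


# ---------------------------------------------------------------------------
# prior building blocks (autodiff side)
# ---------------------------------------------------------------------------

def normal_logpdf_sum(x: ad.Var, mu=0.0, sd=1.0) -> ad.Var:
    if mu == 0.0 and sd == 1.0:
        return ad.neg_half_sumsq(x)
    z = (x - mu) * (1.0 / sd)
    return ad.neg_half_sumsq(z)


def halfnormal_sd(u: ad.Var, scale: float = 2.0):
    """sigma = |u| with u ~ N(0, scale): the folded-normal parameterisation
    of a half-normal(scale) scale parameter; returns (sigma, logp).

    Sampling the unconstrained u and folding gives exactly the half-normal
    law for sigma while avoiding the long left tail (and resulting deep NUTS
    trajectories) of a log-scale parameterisation when the data are weak.
    """
    sigma = ad.absolute(u)
    logp = ad.sumsq(u) * (-0.5 / scale ** 2)
    return sigma, logp


def iid_normal_block(z: ad.Var, sigma: ad.Var):
    """Non-centred scalar random-intercept block; returns (effects, logp(z))."""
    return z * sigma, normal_logpdf_sum(z)


def _cpc_matrices(d: int, eta: float = 2.0):
    """Constant matrices used by the CPC construction for dimension d."""
    m = d * (d - 1) // 2
    embed = np.zeros((d * d, m))
    beta = np.zeros((d, d))
    k = 0
    for i in range(1, d):
        for j in range(i):
            embed[i * d + j, k] = 1.0
            beta[i, j] = eta + (d - 2 - j) / 2.0
            k += 1
    shift = np.zeros((d, d))
    for j in range(1, d):
        shift[j - 1, j] = 1.0
    return embed, beta, shift


def lkj_cholesky(y: ad.Var, d: int, eta: float = 2.0):
    """Cholesky factor of a correlation matrix from unconstrained CPCs.

    `y` has length d(d-1)/2 (strictly-lower entries, row-major).  Returns
    (L, logp) where logp is the LKJ(eta) prior density of the correlation
    matrix expressed in y, including all Jacobian terms: under this
    parameterisation each CPC is an independent scaled Beta, giving
    logp = sum_ij beta_j * log(1 - tanh(y_ij)^2).
    """
    embed, beta, shift = _cpc_matrices(d, eta)
    # shrink fractionally inside (-1, 1) so log1p(-p^2) stays finite even for
    # extreme proposals visited during step-size search
    p = ad.tanh((embed @ y).reshape(d, d)) * (1.0 - 1e-12)
    qlog = ad.log1p(-(p * p)) * 0.5          # 0.5 log(1 - p^2), zero off-mask
    logp = (qlog * (2.0 * beta)).sum()
    c = ad.cumsum(qlog, axis=1)
    c_shift = c @ shift
    eye = np.eye(d)
    L = (p + eye) * ad.exp(c_shift)
    return L, logp


def correlated_effects(z: ad.Var, L: ad.Var, tau: ad.Var):
    """Non-centred correlated random-effects block.

    z: (G, d) standard-normal innovations; tau: (d,) SDs; L: correlation
    Cholesky.  Effects_g = diag(tau) L z_g.  Returns (effects (G, d), logp(z)).
    """
    eff = (z @ L.T) * tau
    return eff, normal_logpdf_sum(z)


# ---------------------------------------------------------------------------
# posterior container and sampling driver
# ---------------------------------------------------------------------------

@dataclass
class Posterior:
    """MCMC output: named draws of shape (chain, draw, ...) + diagnostics."""

    draws: dict
    rhat: dict
    ess_bulk: dict
    n_divergent: int
    layout: ParamLayout = None
    raw: np.ndarray = None  # (chain, draw, dim) unconstrained draws
    sampler_stats: list = None

    def stacked(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape((-1,) + d.shape[2:])

    @property
    def max_rhat(self) -> float:
        if not self.rhat:
            raise RuntimeError("fit was run without diagnostics")
        return max(float(np.nanmax(np.atleast_1d(v)))
                   for v in self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(float(np.nanmin(np.atleast_1d(v)))
                   for v in self.ess_bulk.values())

    def check_convergence(self, rhat_max: float = 1.05) -> None:
        if self.max_rhat > rhat_max:
            worst = {k: float(np.nanmax(np.atleast_1d(v)))
                     for k, v in self.rhat.items()}
            worst = dict(sorted(worst.items(), key=lambda kv: -kv[1])[:5])
            raise RuntimeError(
                f"MCMC did not converge: max split-Rhat {self.max_rhat:.3f} "
                f"> {rhat_max}; worst blocks {worst}")


def _split_rhat_ess(x: np.ndarray):
    """Split-Rhat and bulk-ESS via arviz for draws (chain, draw, ...)."""
    import arviz as az
    ds = az.convert_to_dataset(x)
    return (np.asarray(az.rhat(ds).x.values),
            np.asarray(az.ess(ds, method="bulk").x.values))


def run_mcmc(logp_builder, layout: ParamLayout, transform, *, n_chains=2,
             n_warmup=400, n_draws=400, seed=0, target_accept=0.8,
             max_treedepth=10, init=None, diagnostics=True,
             dense_mass=None) -> Posterior:
    """Fit a model: build logp once, run chains, transform to named draws.

    logp_builder: callable (leaf Var) -> scalar Var log posterior.
    transform: callable (layout, raw draws (chain, draw, dim)) -> dict of
        named draws on the constrained scale.
    """
    vg = ad.value_and_grad(logp_builder)
    raw, stats = sample_nuts(vg, layout.size, n_chains=n_chains,
                             n_warmup=n_warmup, n_draws=n_draws, seed=seed,
                             target_accept=target_accept,
                             max_treedepth=max_treedepth, init=init,
                             dense_mass=dense_mass)
    named = transform(layout, raw)
    rhat, ess = {}, {}
    if diagnostics:
        for k, v in named.items():
            r, e = _split_rhat_ess(v)
            rhat[k] = r
            ess[k] = e
    return Posterior(draws=named, rhat=rhat, ess_bulk=ess,
                     n_divergent=sum(s.n_divergent for s in stats),
                     layout=layout, raw=raw, sampler_stats=stats)
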