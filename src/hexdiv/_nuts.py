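"""No-U-Turn sampler with dual-averaging step-size and windowed mass-matrix
adaptation (diagonal or dense).

A compact, dependency-free implementation of multinomial NUTS (dynamic
Hamiltonian Monte Carlo).  The target is supplied as a callable returning the
log density and its gradient at a point; all models in this package provide
that pair through the package's reverse-mode autodiff.  Hierarchical
regression posteriors in this package carry strong linear correlations
(ridges between global and group-level effects), so a dense inverse mass
matrix estimated during warmup — shrunk towards its diagonal — is the
default for moderate dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular


@dataclass
class SamplerStats:
    accept_prob: np.ndarray = None
    n_divergent: int = 0
    step_size: float = float("nan")
    tree_depth: np.ndarray = None
    mass: object = None


class Mass:
    """Inverse mass matrix (posterior covariance estimate).

    kinetic(r) = 0.5 r' Minv r; momentum ~ N(0, Minv^{-1}).  Three kinds:
    diagonal (vector inv), dense (matrix inv), and block-diagonal (stacked
    (R, q, q) blocks — used when the target is a product of R independent
    replicate posteriors).
    """

    def __init__(self, dim, inv=None, kind="diag"):
        self.dim = dim
        self.kind = kind
        if inv is None:
            inv = np.ones(dim)
            kind = self.kind = "diag"
        self.inv = inv
        if kind == "dense":
            # inv = Sigma = L L'; momentum r = L^{-T} xi
            self._L = np.linalg.cholesky(inv)
        elif kind == "block":
            self._L = np.linalg.cholesky(inv)   # (R, q, q)
            self._R, self._q = inv.shape[0], inv.shape[1]

    def vmult(self, r):
        if self.kind == "dense":
            return self.inv @ r
        if self.kind == "block":
            rb = r.reshape(self._R, self._q)
            return np.einsum("rij,rj->ri", self.inv, rb).ravel()
        return self.inv * r

    def kinetic(self, r):
        return 0.5 * float(np.dot(r, self.vmult(r)))

    def sample_momentum(self, rng):
        xi = rng.standard_normal(self.dim)
        if self.kind == "dense":
            return solve_triangular(self._L, xi, lower=True, trans="T")
        if self.kind == "block":
            xb = xi.reshape(self._R, self._q)
            out = np.linalg.solve(np.transpose(self._L, (0, 2, 1)), xb[..., None])
            return out[..., 0].ravel()
        return xi / np.sqrt(self.inv)


@dataclass
class _DualAveraging:
    """Nesterov dual averaging on log step size (Hoffman & Gelman 2014)."""

    mu: float
    target: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self._t += 1
        eta = 1.0 / (self._t + self.t0)
        self._h_bar = (1 - eta) * self._h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self._t) / self.gamma * self._h_bar
        w = self._t ** -self.kappa
        self._log_eps_bar = w * log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


class _Tree:
    __slots__ = ("theta_minus", "r_minus", "grad_minus", "theta_plus",
                 "r_plus", "grad_plus", "theta_prop", "grad_prop",
                 "logp_prop", "log_weight", "sum_accept", "n_steps",
                 "diverged", "turned")


def _leapfrog(logp_grad, theta, r, grad, eps, mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * mass.vmult(r1)
    logp1, grad1 = logp_grad(theta1)
    r2 = r1 + 0.5 * eps * grad1
    return theta1, r2, logp1, grad1


class NUTS:
    """Single-chain NUTS kernel with windowed mass adaptation."""

    def __init__(self, logp_grad, dim, target_accept=0.8, max_treedepth=10,
                 dense_mass=None, mass_block=None):
        self.logp_grad = logp_grad
        self.dim = dim
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.mass_block = mass_block
        if dense_mass is None:
            dense_mass = dim <= 500
        self.dense_mass = dense_mass and dim > 1

    def run(self, x0, n_warmup, n_draws, rng, step_size=0.1, mass=None,
            adapt_mass=True):
        """Run one chain.  Passing `mass` (and adapt_mass=False) warm-starts
        from a previously adapted mass matrix; only the step size is then
        re-tuned during warmup — used for sweeps over replicate posteriors
        that share a design."""
        if mass is None:
            mass = Mass(self.dim)
        theta = np.asarray(x0, dtype=float).copy()
        logp, grad = self.logp_grad(theta)
        if not np.isfinite(logp):
            raise ValueError("non-finite log density at the initial point")

        step_size = self._find_initial_step(theta, logp, grad, step_size,
                                            mass, rng)
        da = _DualAveraging(mu=np.log(10.0 * step_size),
                            target=self.target_accept)

        w_lo = int(0.05 * n_warmup)
        # expanding adaptation windows: early rough estimates bring the step
        # size up quickly, later ones refine the covariance
        checkpoints = {int(f * n_warmup) - 1
                       for f in (0.20, 0.45, 0.80)} if adapt_mass else set()
        w_hi = int(0.80 * n_warmup)
        buf = []

        draws = np.empty((n_draws, self.dim))
        accepts = np.empty(n_draws)
        depths = np.empty(n_draws, dtype=int)
        n_div = 0

        for it in range(n_warmup + n_draws):
            theta, logp, grad, accept, depth, diverged = self._transition(
                theta, logp, grad, step_size, mass, rng)
            if it < n_warmup:
                step_size = da.update(accept)
                if w_lo <= it < w_hi:
                    buf.append(theta.copy())
                if it in checkpoints and len(buf) > 10:
                    mass = self._estimate_mass(np.asarray(buf))
                    step_size = self._find_initial_step(
                        theta, logp, grad, da.adapted, mass, rng)
                    da = _DualAveraging(mu=np.log(10.0 * step_size),
                                        target=self.target_accept)
                if it == n_warmup - 1:
                    step_size = da.adapted
            else:
                k = it - n_warmup
                draws[k] = theta
                accepts[k] = accept
                depths[k] = depth
                n_div += int(diverged)

        return draws, SamplerStats(accept_prob=accepts, n_divergent=n_div,
                                   step_size=step_size, tree_depth=depths,
                                   mass=mass)

    # ------------------------------------------------------------------

    def _estimate_mass(self, samples: np.ndarray) -> Mass:
        n = len(samples)
        var = samples.var(axis=0, ddof=1)
        # Stan-style regularisation towards unit scale
        var = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
        if self.mass_block is not None:
            q = self.mass_block
            r_blocks = self.dim // q
            sb = samples.reshape(n, r_blocks, q)
            mu = sb.mean(axis=0)
            xc = sb - mu
            cov = np.einsum("nri,nrj->rij", xc, xc) / max(n - 1, 1)
            lam = n / (n + 5.0)
            shrink = n / (n + q)
            dv = np.maximum(var.reshape(r_blocks, q), 1e-10)
            for r in range(r_blocks):
                cov[r] = lam * cov[r] + (1 - lam) * np.diag(dv[r])
                cov[r] = shrink * cov[r] + (1 - shrink) * np.diag(np.diag(cov[r]))
                cov[r][np.diag_indices(q)] += 1e-8
            try:
                return Mass(self.dim, cov, kind="block")
            except np.linalg.LinAlgError:
                return Mass(self.dim, np.maximum(var, 1e-10))
        if not self.dense_mass:
            return Mass(self.dim, np.maximum(var, 1e-10))
        cov = np.cov(samples.T)
        lam = n / (n + 5.0)
        cov = lam * cov + (1 - lam) * np.diag(np.maximum(var, 1e-10))
        # shrink off-diagonals further when the sample is small relative to
        # the dimension, keeping the estimate well conditioned
        shrink = n / (n + self.dim)
        cov = shrink * cov + (1 - shrink) * np.diag(np.diag(cov))
        cov[np.diag_indices(self.dim)] += 1e-8
        try:
            return Mass(self.dim, cov, kind="dense")
        except np.linalg.LinAlgError:
            return Mass(self.dim, np.maximum(var, 1e-10))

    def _find_initial_step(self, theta, logp, grad, eps, mass, rng):
        eps = float(eps)
        r = mass.sample_momentum(rng)
        h0 = logp - mass.kinetic(r)
        _, r1, logp1, _ = _leapfrog(self.logp_grad, theta, r, grad, eps, mass)
        h1 = logp1 - mass.kinetic(r1) if np.isfinite(logp1) else -np.inf
        d_h = h1 - h0
        direction = 1.0 if d_h > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0 ** direction
            _, r1, logp1, _ = _leapfrog(self.logp_grad, theta, r, grad, eps,
                                        mass)
            h1 = logp1 - mass.kinetic(r1) if np.isfinite(logp1) else -np.inf
            if direction * (h1 - h0) < direction * np.log(0.5):
                break
        return eps

    def _transition(self, theta, logp, grad, eps, mass, rng):
        r0 = mass.sample_momentum(rng)
        h0 = logp - mass.kinetic(r0)

        tree = _Tree()
        tree.theta_minus = tree.theta_plus = tree.theta_prop = theta
        tree.r_minus = tree.r_plus = r0
        tree.grad_minus = tree.grad_plus = tree.grad_prop = grad
        tree.logp_prop = logp
        tree.log_weight = 0.0
        tree.sum_accept = 0.0
        tree.n_steps = 0
        tree.diverged = False
        tree.turned = False

        depth = 0
        while depth < self.max_treedepth:
            go_right = rng.random() < 0.5
            if go_right:
                sub = self._build_tree(tree.theta_plus, tree.r_plus,
                                       tree.grad_plus, +1, depth, eps, mass,
                                       h0, rng)
                tree.theta_plus = sub.theta_plus
                tree.r_plus = sub.r_plus
                tree.grad_plus = sub.grad_plus
            else:
                sub = self._build_tree(tree.theta_minus, tree.r_minus,
                                       tree.grad_minus, -1, depth, eps, mass,
                                       h0, rng)
                tree.theta_minus = sub.theta_minus
                tree.r_minus = sub.r_minus
                tree.grad_minus = sub.grad_minus
            tree.sum_accept += sub.sum_accept
            tree.n_steps += sub.n_steps
            if sub.diverged or sub.turned:
                tree.diverged = tree.diverged or sub.diverged
                break
            log_ratio = sub.log_weight - tree.log_weight
            if np.log(rng.random() + 1e-300) < log_ratio:
                tree.theta_prop = sub.theta_prop
                tree.grad_prop = sub.grad_prop
                tree.logp_prop = sub.logp_prop
            tree.log_weight = np.logaddexp(tree.log_weight, sub.log_weight)
            if self._uturn(tree.theta_minus, tree.theta_plus, tree.r_minus,
                           tree.r_plus, mass):
                depth += 1
                break
            depth += 1

        accept = tree.sum_accept / max(tree.n_steps, 1)
        return (tree.theta_prop, tree.logp_prop, tree.grad_prop, accept,
                depth, tree.diverged)

    def _build_tree(self, theta, r, grad, direction, depth, eps, mass, h0,
                    rng):
        if depth == 0:
            t1, r1, logp1, g1 = _leapfrog(self.logp_grad, theta, r, grad,
                                          direction * eps, mass)
            h1 = logp1 - mass.kinetic(r1) if np.isfinite(logp1) else -np.inf
            d_h = h1 - h0
            sub = _Tree()
            sub.theta_minus = sub.theta_plus = sub.theta_prop = t1
            sub.r_minus = sub.r_plus = r1
            sub.grad_minus = sub.grad_plus = sub.grad_prop = g1
            sub.logp_prop = logp1
            sub.log_weight = d_h if np.isfinite(d_h) else -np.inf
            sub.sum_accept = float(min(1.0, np.exp(min(d_h, 0.0))))
            sub.n_steps = 1
            sub.diverged = d_h < -1000.0
            sub.turned = False
            return sub

        first = self._build_tree(theta, r, grad, direction, depth - 1, eps,
                                 mass, h0, rng)
        if first.diverged or first.turned:
            return first
        if direction > 0:
            second = self._build_tree(first.theta_plus, first.r_plus,
                                      first.grad_plus, direction, depth - 1,
                                      eps, mass, h0, rng)
            first.theta_plus = second.theta_plus
            first.r_plus = second.r_plus
            first.grad_plus = second.grad_plus
        else:
            second = self._build_tree(first.theta_minus, first.r_minus,
                                      first.grad_minus, direction, depth - 1,
                                      eps, mass, h0, rng)
            first.theta_minus = second.theta_minus
            first.r_minus = second.r_minus
            first.grad_minus = second.grad_minus
        first.sum_accept += second.sum_accept
        first.n_steps += second.n_steps
        first.diverged = first.diverged or second.diverged
        if not first.diverged:
            log_ratio = second.log_weight - np.logaddexp(first.log_weight,
                                                         second.log_weight)
            if np.log(rng.random() + 1e-300) < log_ratio:
                first.theta_prop = second.theta_prop
                first.grad_prop = second.grad_prop
                first.logp_prop = second.logp_prop
            first.log_weight = np.logaddexp(first.log_weight,
                                            second.log_weight)
            first.turned = second.turned or self._uturn(
                first.theta_minus, first.theta_plus, first.r_minus,
                first.r_plus, mass)
        return first

    @staticmethod
    def _uturn(theta_minus, theta_plus, r_minus, r_plus, mass):
        delta = theta_plus - theta_minus
        return (np.dot(delta, mass.vmult(r_minus)) < 0.0
                or np.dot(delta, mass.vmult(r_plus)) < 0.0)


def sample_nuts(logp_grad, dim, *, n_chains=2, n_warmup=400, n_draws=400,
                seed=0, init=None, target_accept=0.8, max_treedepth=10,
                init_jitter=0.5, dense_mass=None, mass_block=None):
    """Run several NUTS chains; returns (draws (chain, draw, dim), stats)."""
    kernel = NUTS(logp_grad, dim, target_accept=target_accept,
                  max_treedepth=max_treedepth, dense_mass=dense_mass,
                  mass_block=mass_block)
    all_draws = np.empty((n_chains, n_draws, dim))
    stats = []
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        if init is None:
            x0 = init_jitter * rng.standard_normal(dim)
        else:
            x0 = np.asarray(init, dtype=float) \
                + init_jitter * rng.standard_normal(dim)
        draws, st = kernel.run(x0, n_warmup, n_draws, rng)
        all_draws[c] = draws
        stats.append(st)
    return all_draws, stats
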