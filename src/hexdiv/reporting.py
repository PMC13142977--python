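"""Posterior summarisation and interpretation utilities.

Conventions: posterior intervals are highest-posterior-density intervals
(HPDI), by default covering 89% of the posterior mass; effect sizes on the
logit scale can be converted to changes on the normalized-entropy probability
scale and to an equivalent number of "maximally variable" binary features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import normalized_entropy


@dataclass(frozen=True)
class HPDISummary:
    mass: float
    lower: float
    upper: float
    multimodal_flag: bool = False


def hpdi(draws, mass: float = 0.89) -> HPDISummary:
    """Shortest contiguous interval containing `mass` of the draws.

    Computed by exhaustive scan over contiguous windows of the sorted draws;
    the standard single-interval HPDI convention.  A crude unimodality
    heuristic flags draw sets where the shortest window may be misleading.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 10:
        raise ValueError("need at least 10 draws")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(draws)
    n = x.size
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    lower, upper = float(x[i]), float(x[i + k - 1])
    # unimodality heuristic: histogram with a dip of > 50% between two peaks
    flag = False
    if n >= 100:
        hist, _ = np.histogram(x, bins=max(10, n // 50))
        smoothed = np.convolve(hist, np.ones(3) / 3.0, mode="same")
        peak = smoothed.max()
        imax = int(np.argmax(smoothed))
        left_max = smoothed[:imax].max() if imax > 0 else 0.0
        right_max = smoothed[imax + 1:].max() if imax < len(smoothed) - 1 else 0.0
        interior = smoothed[min(imax, 1):max(imax, len(smoothed) - 1)]
        if interior.size and (interior.min() < 0.5 * min(peak, max(left_max, right_max, 1e-12))
                              and max(left_max, right_max) > 0.6 * peak):
            flag = smoothed.argmin() not in (0, len(smoothed) - 1)
    return HPDISummary(mass=mass, lower=lower, upper=upper,
                       multimodal_flag=bool(flag))


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def effect_on_probability_scale(baseline_hn: float, delta_logit: float) -> float:
    """Change in normalized entropy implied by a logit-scale shift.

    inverse-logit(logit(baseline) + delta) - baseline; e.g. a 0.11 logit
    increase at a 0.291 baseline is worth about +0.023 (2.3 percentage
    points) of normalized entropy.
    """
    if not (0.0 < baseline_hn < 1.0):
        raise ValueError("baseline must lie strictly inside (0, 1)")
    return float(_inv_logit(_logit(baseline_hn) + delta_logit) - baseline_hn)


def entropy_change_to_feature_count(delta_hn: float, n_features: int,
                                    p_low: float) -> int:
    """Equivalent number of binary features made maximally variable.

    Interprets a gain `delta_hn` in average normalized entropy over
    `n_features` binary features as the count of features whose state
    distribution moves from a rare state at probability `p_low` (low entropy)
    to 0.5/0.5 (entropy 1).
    """
    if delta_hn < 0:
        raise ValueError("delta_hn must be non-negative")
    if not (0.0 < p_low < 0.5):
        raise ValueError("p_low must lie in (0, 0.5)")
    per_feature_gain = 1.0 - normalized_entropy([p_low, 1.0 - p_low])
    return int(round(delta_hn * n_features / per_feature_gain))


def posterior_prob_positive(draws) -> float:
    """Fraction of posterior draws above zero."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 10:
        raise ValueError("need at least 10 draws")
    return float(np.mean(draws > 0.0))


def summarize_draws(draws, masses=(0.5, 0.89, 0.95)) -> dict:
    """Posterior mean/median/SD plus HPDIs and P(>0) for a 1-D draw vector."""
    draws = np.asarray(draws, dtype=float).ravel()
    out = {
        "mean": float(draws.mean()),
        "median": float(np.median(draws)),
        "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        "p_positive": posterior_prob_positive(draws),
    }
    for m in masses:
        h = hpdi(draws, m)
        pct = int(round(100 * m))
        out[f"hpdi{pct}_lower"] = h.lower
        out[f"hpdi{pct}_upper"] = h.upper
    return out
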