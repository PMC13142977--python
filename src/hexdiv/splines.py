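"""Tensor-product B-spline bases for spatial smooths.

The two-dimensional smooth over projected (Equal Earth) cell-centroid
coordinates is a tensor product of two marginal cubic B-spline bases; the
coefficients receive a shared zero-mean normal prior whose SD is itself a
model parameter (the "spline SD").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


def _open_uniform_knots(lo: float, hi: float, n_basis: int, degree: int):
    if hi - lo < 1e-9:
        hi = lo + 1.0
    n_break = n_basis - degree + 1
    if n_break < 2:
        raise ValueError("n_basis too small for the requested degree")
    breaks = np.linspace(lo, hi, n_break)
    return np.concatenate([np.full(degree, lo), breaks, np.full(degree, hi)])


@dataclass
class TensorSpline:
    """Tensor product of marginal cubic B-spline bases on planar coordinates.

    Inputs outside the fitted range are clamped to the boundary, so
    prediction at new locations is always defined.
    """

    knots_x: np.ndarray
    knots_y: np.ndarray
    degree: int = 3

    @classmethod
    def fit_domain(cls, x, y, n_basis: int = 5, degree: int = 3):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pad_x = 1e-6 + 0.01 * (x.max() - x.min())
        pad_y = 1e-6 + 0.01 * (y.max() - y.min())
        return cls(
            knots_x=_open_uniform_knots(x.min() - pad_x, x.max() + pad_x,
                                        n_basis, degree),
            knots_y=_open_uniform_knots(y.min() - pad_y, y.max() + pad_y,
                                        n_basis, degree),
            degree=degree)

    @property
    def n_basis_x(self) -> int:
        return len(self.knots_x) - self.degree - 1

    @property
    def n_basis_y(self) -> int:
        return len(self.knots_y) - self.degree - 1

    @property
    def n_coef(self) -> int:
        return self.n_basis_x * self.n_basis_y

    def basis(self, x, y) -> np.ndarray:
        """Design matrix of shape (n, n_basis_x * n_basis_y)."""
        x = np.clip(np.asarray(x, dtype=float),
                    self.knots_x[0], self.knots_x[-1] - 1e-12)
        y = np.clip(np.asarray(y, dtype=float),
                    self.knots_y[0], self.knots_y[-1] - 1e-12)
        bx = BSpline.design_matrix(x, self.knots_x, self.degree).toarray()
        by = BSpline.design_matrix(y, self.knots_y, self.degree).toarray()
        return (bx[:, :, None] * by[:, None, :]).reshape(len(x), -1)
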