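"""Basis and penalty construction for additive model terms.

Supports four functional forms per covariate: identity (``I``),
orthogonal polynomials of degree 2/3 (``poly2``/``poly3``) and a
penalized cubic regression spline (``s``) with knots at quantiles of
the observed values, a second-derivative (curvature) penalty and a
sum-to-zero identifiability constraint.  The spline interpolates values
at the knots with a natural cubic spline, so extrapolation beyond the
boundary knots is linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BasisError


def crs_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Knots at evenly spaced quantiles of the distinct covariate values."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise BasisError(
            f"only {ux.size} distinct values but spline basis dimension k={k}; reduce k"
        )
    qs = np.linspace(0, 1, k)
    knots = np.quantile(ux, qs, method="linear")
    # quantiles of nearly-discrete data can coincide; nudge to distinct
    if np.unique(knots).size < k:
        knots = np.linspace(ux[0], ux[-1], k)
    return knots


def _crs_F(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map values-at-knots to second derivatives; return (F_full, S).

    ``F_full`` is (k, k) with zero first/last rows (natural boundary);
    ``S = D' B^-1 D`` is the curvature penalty of rank k-2.
    """
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv = np.linalg.inv(B)
    F = Binv @ D
    F_full = np.vstack([np.zeros(k), F, np.zeros(k)])
    S = D.T @ Binv @ D
    return F_full, S


def crs_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the cardinal natural-cubic-spline basis at ``x``.

    Returns the (n, k) matrix mapping values at the knots to f(x);
    linear extension beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    k = knots.size
    h = np.diff(knots)
    F_full, _ = _crs_F(knots)
    N = np.zeros((x.size, k))
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    inside = (x >= knots[0]) & (x <= knots[-1])
    if inside.any():
        ii = np.flatnonzero(inside)
        jj = j[ii]
        hj = h[jj]
        dr = knots[jj + 1] - x[ii]  # distance to right knot
        dl = x[ii] - knots[jj]
        am = dr / hj
        ap = dl / hj
        cm = (dr**3 / hj - hj * dr) / 6.0
        cp = (dl**3 / hj - hj * dl) / 6.0
        N[ii] = cm[:, None] * F_full[jj] + cp[:, None] * F_full[jj + 1]
        N[ii, jj] += am
        N[ii, jj + 1] += ap
    # linear extrapolation: f(x0) + (x - x0) f'(x0)
    left = x < knots[0]
    if left.any():
        slope = np.zeros(k)
        slope[0] -= 1.0 / h[0]
        slope[1] += 1.0 / h[0]
        slope -= h[0] / 6.0 * (2 * F_full[0] + F_full[1])
        base = np.zeros(k)
        base[0] = 1.0
        N[left] = base + np.outer(x[left] - knots[0], slope)
    right = x > knots[-1]
    if right.any():
        slope = np.zeros(k)
        slope[-2] -= 1.0 / h[-1]
        slope[-1] += 1.0 / h[-1]
        slope += h[-1] / 6.0 * (F_full[-2] + 2 * F_full[-1])
        base = np.zeros(k)
        base[-1] = 1.0
        N[right] = base + np.outer(x[right] - knots[-1], slope)
    return N


def crs_penalty(knots: np.ndarray) -> np.ndarray:
    """Curvature penalty in the values-at-knots parameterization."""
    return _crs_F(knots)[1]


def sum_to_zero_constraint(col_means: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the row vector of means.

    Reparameterizing the spline as ``N @ Z`` makes its column means zero
    on the training rows, absorbing the function's constant into the
    model intercept (dimension drops by one).
    """
    c = np.atleast_2d(col_means)
    _, _, vt = np.linalg.svd(c)
    return vt[1:].T  # (k, k-1)


@dataclass
class OrthoPoly:
    """Orthogonalized polynomial columns with a stored linear map.

    Training columns are the Q factor of the centered Vandermonde
    matrix; new data reuse the training means and map, so predictions
    are exactly the same polynomial whichever basis is used.
    """

    degree: int
    means: np.ndarray = field(default=None)
    transform: np.ndarray = field(default=None)

    def fit(self, x: np.ndarray) -> np.ndarray:
        V = np.column_stack([np.asarray(x, float) ** d for d in range(1, self.degree + 1)])
        self.means = V.mean(axis=0)
        Vc = V - self.means
        q, r = np.linalg.qr(Vc)
        if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
            raise BasisError(f"degree-{self.degree} polynomial is rank deficient on these values")
        self.transform = np.linalg.inv(r) * np.sqrt(len(x))
        return Vc @ self.transform

    def apply(self, x: np.ndarray) -> np.ndarray:
        V = np.column_stack([np.asarray(x, float) ** d for d in range(1, self.degree + 1)])
        return (V - self.means) @ self.transform
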