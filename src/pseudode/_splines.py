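"""Cubic spline bases for smooth-of-pseudotime terms.

The smooth f(T) is represented in a cubic B-spline basis with knots at
quantiles of the observed pseudotime, penalized by the integrated squared
second derivative, and centered (sum-to-zero over the observed cells) so the
smooth is identifiable next to a separate intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class DegenerateBasisError(ValueError):
    """Raised when pseudotime has too few distinct values to build a basis."""


# 2-point Gauss-Legendre nodes/weights on [-1, 1]; exact for the piecewise
# quadratic integrands arising from products of B-spline second derivatives.
_GAUSS_X = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS_W = np.array([1.0, 1.0])


def _bspline_design(x: np.ndarray, t: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Dense design matrix of all cubic B-splines on knot vector t at points x."""
    n_basis = len(t) - 4
    if deriv == 0:
        d = BSpline.design_matrix(x, t, 3, extrapolate=False)
        return np.asarray(d.todense())
    out = np.empty((len(x), n_basis))
    eye = np.eye(n_basis)
    for k in range(n_basis):
        out[:, k] = BSpline(t, eye[k], 3).derivative(deriv)(x)
    return out


@dataclass
class SplineBasis:
    """Centered cubic spline basis evaluated at the observed pseudotime.

    Attributes
    ----------
    knots : interior+boundary knot locations (quantiles of T).
    design : n x p centered basis matrix (column sums ~ 0).
    penalty : p x p integrated-squared-second-derivative penalty, transformed
        by the same centering map and scaled to unit spectral norm.
    constraint : (p+1) x p null-space map applied to the raw basis.
    """

    knots: np.ndarray
    design: np.ndarray
    penalty: np.ndarray
    constraint: np.ndarray
    _knot_vector: np.ndarray = field(repr=False)
    _q: np.ndarray = field(repr=False, default=None)
    _r: np.ndarray = field(repr=False, default=None)

    @property
    def n_basis(self) -> int:
        return self.design.shape[1]

    def evaluate(self, T: np.ndarray) -> np.ndarray:
        """Centered design rows at (possibly new) pseudotime values."""
        T = np.clip(np.asarray(T, float), self.knots[0], self.knots[-1])
        raw = _bspline_design(T, self._knot_vector)
        return raw @ self.constraint

    def qr(self) -> tuple[np.ndarray, np.ndarray]:
        """Economy QR of the centered design (cached)."""
        if self._q is None:
            self._q, self._r = np.linalg.qr(self.design)
        return self._q, self._r


def build_spline_basis(T, K: int = 6) -> SplineBasis:
    """Build the centered, penalized cubic spline basis for pseudotime T.

    Knots sit at K quantiles of T (mgcv's convention for cubic regression
    splines); duplicated quantiles are collapsed, reducing K with a warning,
    down to a minimum of 3 distinct knots.
    """
    T = np.asarray(getattr(T, "values", T), dtype=float).ravel()
    if np.unique(T).size < 3:
        raise DegenerateBasisError(
            "need at least 3 distinct pseudotime values to build a spline basis"
        )
    knots = np.quantile(T, np.linspace(0.0, 1.0, K))
    knots = np.unique(knots)
    if len(knots) < K:
        if len(knots) < 3:
            raise DegenerateBasisError("fewer than 3 distinct knot locations")
        warnings.warn(
            f"duplicated knot quantiles: K reduced from {K} to {len(knots)}",
            stacklevel=2,
        )
    # boundary knots repeated to multiplicity 4 for a cubic basis
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    X_raw = _bspline_design(np.clip(T, knots[0], knots[-1]), t)

    # exact integral of B_i'' B_j'' via per-interval 2-pt Gauss quadrature
    p_raw = X_raw.shape[1]
    P_raw = np.zeros((p_raw, p_raw))
    for a, b in zip(knots[:-1], knots[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts = mid + half * _GAUSS_X
        D2 = _bspline_design(pts, t, deriv=2)
        P_raw += half * (D2.T * _GAUSS_W) @ D2

    # sum-to-zero centering: project onto the null space of the column means
    c = X_raw.mean(axis=0)
    Qc = np.linalg.qr(c.reshape(-1, 1), mode="complete")[0]
    Z = Qc[:, 1:]
    X = X_raw @ Z
    P = Z.T @ P_raw @ Z
    P = 0.5 * (P + P.T)
    top = np.linalg.eigvalsh(P)[-1]
    if top > 0:
        P = P / top
    return SplineBasis(knots=knots, design=X, penalty=P, constraint=Z, _knot_vector=t)
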