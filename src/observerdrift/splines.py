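"""Low-level P-spline building blocks shared by the smoothing and GAMM engines.

Cubic B-spline bases on uniform knots with difference penalties (P-splines).
The order-2 difference penalty has a null space spanned by constant and
linear functions of the covariate, so letting the smoothing parameter go to
infinity collapses a smooth term to a straight line.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def uniform_knots(xmin: float, xmax: float, k: int, degree: int = 3) -> np.ndarray:
    """Uniform knot vector giving exactly ``k`` B-spline basis functions.

    The interior range [xmin, xmax] is padded with ``degree`` knots on each
    side so the basis is well defined on the closed interval.
    """
    if k <= degree:
        raise ValueError(f"need k > degree, got k={k}, degree={degree}")
    if not xmax > xmin:
        raise ValueError("xmax must exceed xmin")
    n_interior = k - degree + 1
    inner = np.linspace(xmin, xmax, n_interior)
    step = inner[1] - inner[0] if n_interior > 1 else (xmax - xmin) or 1.0
    left = xmin - step * np.arange(degree, 0, -1)
    right = xmax + step * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Dense B-spline design matrix; values clipped to the knot support."""
    x = np.asarray(x, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """Penalty matrix D'D for order-``order`` differences of k coefficients."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def centering_constraint(B: np.ndarray) -> np.ndarray:
    """Reparameterization Z removing the sum-to-zero constrained direction.

    Returns Z (k x k-1) with columns orthogonal to the column-sum vector of B,
    so that columns of B @ Z each sum to zero. Keeps the model identifiable
    next to an explicit intercept.
    """
    c = B.sum(axis=0)
    q, _ = np.linalg.qr(c[:, None], mode="complete")
    return q[:, 1:]


class SmoothTerm:
    """A centered penalized spline term for one covariate.

    Parameters
    ----------
    x : array
        Covariate values (training data).
    k : int
        Basis dimension before centering.
    degree, penalty_order : int
        B-spline degree and difference-penalty order.
    linear : bool
        If True the term is the penalty null space itself (a centered linear
        column, zero penalty) -- the infinite-smoothing limit.
    """

    def __init__(self, x, k: int = 10, degree: int = 3, penalty_order: int = 2,
                 linear: bool = False):
        x = np.asarray(x, dtype=float)
        self.xmin = float(np.min(x))
        self.xmax = float(np.max(x))
        self.degree = degree
        self.linear = linear
        if self.xmax <= self.xmin:
            raise ValueError("smooth covariate is constant; cannot build a basis")
        if linear:
            self.knots = None
            self.Z = None
            self._xmean = float(np.mean(x))
            self.ncoef = 1
            self.penalty = np.zeros((1, 1))
            return
        n_unique = np.unique(x).size
        k = int(min(k, max(n_unique, degree + 1)))
        if k <= degree:
            raise ValueError(
                f"covariate has {n_unique} unique values; too few for a "
                f"degree-{degree} spline basis"
            )
        self.knots = uniform_knots(self.xmin, self.xmax, k, degree)
        B = bspline_design(x, self.knots, degree)
        self.Z = centering_constraint(B)
        self.ncoef = self.Z.shape[1]
        S = difference_penalty(k, penalty_order)
        self.penalty = self.Z.T @ S @ self.Z

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.linear:
            return (x - self._xmean)[:, None]
        return bspline_design(x, self.knots, self.degree) @ self.Z
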