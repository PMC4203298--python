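"""Weighted one-dimensional penalized-spline smoother (Gaussian errors).

Used for the second-stage group curves and for the meta-regressions of
coefficient estimates / population trends on peak vocalization frequency.
Smoothing parameter chosen by GCV on a log grid; the smooth-term p-value is
an approximate F test comparing the fitted smooth to the intercept-only
model at the effective degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .splines import SmoothTerm

_LAMBDA_GRID = np.logspace(-6, 8, 57)


@dataclass
class WeightedFit:
    """Result of a weighted smooth or linear fit on one predictor."""

    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    grid: np.ndarray
    fitted_grid: np.ndarray
    se_grid: np.ndarray
    intercept: float
    intercept_se: float
    intercept_p: float
    smooth_p: float
    edf: float
    lambda_: float
    n: int
    scale: float
    coef: np.ndarray = field(repr=False, default=None)

    @property
    def band_lo(self) -> np.ndarray:
        return self.fitted_grid - 1.96 * self.se_grid

    @property
    def band_hi(self) -> np.ndarray:
        return self.fitted_grid + 1.96 * self.se_grid

    def predict(self, x_new) -> np.ndarray:
        return np.interp(np.asarray(x_new, dtype=float), self.grid, self.fitted_grid)


def _solve_penalized(X, y, w, S, lam):
    XtW = X.T * w
    A = XtW @ X + lam * S
    coef = np.linalg.solve(A, XtW @ y)
    Ainv = np.linalg.inv(A)
    return coef, Ainv, XtW


def fit_psmooth(x, y, weights=None, k: int = 10, lam=None, n_grid: int = 200,
                linear: bool = False) -> WeightedFit:
    """Fit y = a + f(x) by weighted penalized least squares.

    Parameters
    ----------
    weights : array or None
        Relative inverse-variance weights; normalized to mean 1 internally so
        rescaling all weights leaves the fit unchanged.
    lam : float, np.inf, or None
        Smoothing parameter; None selects by GCV. ``np.inf`` (or
        ``linear=True``) collapses the smooth to its linear null space and
        the result equals closed-form weighted least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        w = w / w.mean()

    if linear or (lam is not None and np.isinf(lam)):
        linear = True
        lam = 0.0
    if np.unique(x).size < 2:
        raise ValueError("predictor is constant")

    kk = min(k, max(np.unique(x).size, 4))
    term = SmoothTerm(x, k=kk, linear=linear)
    Xs = term.design(x)
    X = np.column_stack([np.ones(n), Xs])
    p = X.shape[1]
    if n < p and not linear:
        # shrink basis until identifiable
        while n < p and kk > 4:
            kk -= 1
            term = SmoothTerm(x, k=kk, linear=linear)
            Xs = term.design(x)
            X = np.column_stack([np.ones(n), Xs])
            p = X.shape[1]
    S = np.zeros((p, p))
    S[1:, 1:] = term.penalty

    if lam is None:
        best = (np.inf, None)
        for lg in _LAMBDA_GRID:
            coef, Ainv, XtW = _solve_penalized(X, y, w, S, lg)
            edf = float(np.trace(Ainv @ (XtW @ X)))
            r = y - X @ coef
            rss = float(np.sum(w * r * r))
            denom = max(n - edf, 1e-8) ** 2
            gcv = n * rss / denom
            if gcv < best[0]:
                best = (gcv, lg)
        lam = best[1]

    coef, Ainv, XtW = _solve_penalized(X, y, w, S, lam)
    F_mat = Ainv @ (XtW @ X)
    edf = float(np.trace(F_mat))
    resid = y - X @ coef
    rss = float(np.sum(w * resid * resid))
    scale = rss / max(n - edf, 1.0)

    # Bayesian covariance of coefficients
    Vb = Ainv * scale

    grid = np.linspace(term.xmin, term.xmax, n_grid)
    Xg = np.column_stack([np.ones(grid.size), term.design(grid)])
    fitted_grid = Xg @ coef
    se_grid = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, Vb, Xg), 0.0))

    intercept = float(coef[0])
    intercept_se = float(np.sqrt(max(Vb[0, 0], 0.0)))
    dfres = max(n - edf, 1.0)
    if intercept_se > 0:
        intercept_p = float(2 * stats.t.sf(abs(intercept / intercept_se), dfres))
    else:
        intercept_p = float("nan")

    # F test: intercept-only vs fitted smooth
    ybar = float(np.sum(w * y) / np.sum(w))
    rss0 = float(np.sum(w * (y - ybar) ** 2))
    df1 = max(edf - 1.0, 1.0)
    if rss0 > rss and scale > 0:
        Fstat = ((rss0 - rss) / df1) / scale
        smooth_p = float(stats.f.sf(Fstat, df1, dfres))
    else:
        smooth_p = 1.0

    return WeightedFit(
        x=x, y=y, weights=w, grid=grid, fitted_grid=fitted_grid, se_grid=se_grid,
        intercept=intercept, intercept_se=intercept_se, intercept_p=intercept_p,
        smooth_p=smooth_p, edf=edf, lambda_=float(lam), n=n, scale=scale, coef=coef,
    )
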