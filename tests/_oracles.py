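"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the implementation paths they check: the occupancy
likelihood is recomputed by brute-force enumeration of the latent states,
and weighted least squares / Pearson tests come from the closed-form normal
equations and t-transform.
"""

import numpy as np
from scipy import stats


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def brute_force_loglik(params, squares):
    """Enumerate latent occupancy states exactly.

    ``squares`` is a list of (first_atlas, visits) pairs with visits a list
    of (y, effort, over50, male). ``params`` is (a0, a1, b0, b1, b2, b3).
    """
    a0, a1, b0, b1, b2, b3 = params
    total = 0.0
    for first_atlas, visits in squares:
        psi = float(sigmoid(a0 + a1 * first_atlas))
        lik_occupied = 1.0
        all_zero = True
        for (y, eff, over, male) in visits:
            p = float(sigmoid(b0 + b1 * eff + b2 * over + b3 * male))
            lik_occupied *= p if y else (1.0 - p)
            if y:
                all_zero = False
        lik = psi * lik_occupied + (1.0 - psi) * (1.0 if all_zero else 0.0)
        total += np.log(lik)
    return total


def wls_normal_equations(x, y, w):
    """Closed-form weighted least squares for y = b0 + b1 x.

    Returns (b0, b1, se_b1, p_b1) with the two-sided t test on the slope.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ y)
    resid = y - X @ beta
    n = x.size
    sigma2 = float(np.sum(w * resid ** 2)) / (n - 2)
    cov = np.linalg.inv(A) * sigma2
    se1 = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se1
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(beta[0]), float(beta[1]), se1, float(p)


def pearson_closed_form(x, y):
    """Pearson r via the sum formula and its exact t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    r = sxy / np.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, 0.0
    t = abs(r) * np.sqrt((n - 2) / (1 - r ** 2))
    return r, float(2 * stats.t.sf(t, n - 2))
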