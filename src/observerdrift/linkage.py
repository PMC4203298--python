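"""Linking detection declines to vocalization frequency and published trends.

Four analyses over a per-species table joining the occupancy-model age
contrast (b2, with posterior variance), peak vocalization frequency and
heterogeneity labels, and externally supplied population trends:

* weighted spline smooth of b2 on peak frequency (weights: inverse posterior
  variance), separately for monotone and heterogeneous species, with an
  intercept (central-tendency) test;
* a post-hoc inverse-variance-weighted linear model over monotone species at
  or above 6 kHz;
* weighted spline smooths of population trend on peak frequency (weights:
  inverse 95%-interval width for source A, route counts for source B);
* unweighted Pearson correlations of b2 with trends over the monotone
  >= 6 kHz subset, with a leave-one-out sensitivity table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .smoothing import WeightedFit, fit_psmooth

HIGHFREQ_CUTOFF_KHZ = 6.0

REQUIRED = ("species", "peak_khz", "heterogeneity", "beta2", "beta2_var")


def _check_rows(rows: pd.DataFrame, extra=()):
    missing = [c for c in (*REQUIRED, *extra) if c not in rows.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    if (rows["beta2_var"] <= 0).any():
        raise ValueError("beta2 posterior variances must be positive")


def subset_rows(rows: pd.DataFrame, heterogeneity: str | None = None,
                min_khz: float | None = None) -> pd.DataFrame:
    out = rows
    if heterogeneity is not None:
        out = out[out["heterogeneity"] == heterogeneity]
    if min_khz is not None:
        out = out[out["peak_khz"] >= min_khz]
    return out


def fit_beta2_vs_frequency(rows: pd.DataFrame, subset: str = "monotone",
                           k: int = 10, lam=None) -> WeightedFit:
    """Weighted penalized-spline regression of b2 on peak frequency.

    Weights are inverse posterior variances, normalized to mean 1. The
    intercept estimate and p-value report the central tendency of b2.
    """
    _check_rows(rows)
    sub = subset_rows(rows, heterogeneity=subset)
    if len(sub) < 5:
        raise ValueError(f"need >= 5 species in subset {subset!r}, got {len(sub)}")
    w = 1.0 / sub["beta2_var"].to_numpy(dtype=float)
    return fit_psmooth(sub["peak_khz"].to_numpy(dtype=float),
                       sub["beta2"].to_numpy(dtype=float),
                       weights=w, k=k, lam=lam)


def weighted_linear_fit(x, y, weights) -> dict:
    """Inverse-variance-weighted simple linear regression (statsmodels WLS)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    return {
        "intercept": float(res.params[0]),
        "slope": float(res.params[1]),
        "slope_se": float(res.bse[1]),
        "slope_p": float(res.pvalues[1]),
        "intercept_p": float(res.pvalues[0]),
        "n": int(x.size),
        "result": res,
    }


def posthoc_highfreq_linear(rows: pd.DataFrame) -> dict:
    """Weighted linear model of b2 on peak frequency over monotone species at
    or above 6 kHz; two-sided slope test."""
    _check_rows(rows)
    sub = subset_rows(rows, heterogeneity="monotone", min_khz=HIGHFREQ_CUTOFF_KHZ)
    if len(sub) < 3:
        raise ValueError(
            f"post-hoc model needs >= 3 monotone species at >= 6 kHz, got {len(sub)}")
    fit = weighted_linear_fit(sub["peak_khz"], sub["beta2"],
                              1.0 / sub["beta2_var"].to_numpy(dtype=float))
    fit["species"] = sub["species"].tolist()
    return fit


def fit_trend_vs_frequency(rows: pd.DataFrame, trend_source: str,
                           subset: str = "monotone", k: int = 10,
                           lam=None) -> WeightedFit:
    """Weighted spline smooth of a population trend on peak frequency.

    ``trend_source`` is 'a' (inverse 95%-CI-width weights) or 'b' (route-count
    weights); the table must carry ``trend_<source>`` plus ``trend_a_ci_width``
    or ``trend_b_routes`` respectively.
    """
    if trend_source not in ("a", "b"):
        raise ValueError("trend_source must be 'a' or 'b'")
    tcol = f"trend_{trend_source}"
    wcol = "trend_a_ci_width" if trend_source == "a" else "trend_b_routes"
    _check_rows(rows, extra=(tcol, wcol))
    sub = subset_rows(rows, heterogeneity=subset).dropna(subset=[tcol, wcol])
    if len(sub) < 5:
        raise ValueError(f"need >= 5 species with {tcol}, got {len(sub)}")
    wraw = sub[wcol].to_numpy(dtype=float)
    if np.any(wraw <= 0):
        raise ValueError(f"nonpositive values in weight column {wcol}")
    w = (1.0 / wraw) if trend_source == "a" else wraw
    return fit_psmooth(sub["peak_khz"].to_numpy(dtype=float),
                       sub[tcol].to_numpy(dtype=float), weights=w, k=k, lam=lam)


def pearson_with_p(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_beta2_trend(rows: pd.DataFrame, trend_source: str = "a",
                          min_khz: float = HIGHFREQ_CUTOFF_KHZ) -> dict:
    """Pearson correlation of b2 with a trend source over monotone species at
    or above ``min_khz``, plus a leave-one-out sensitivity table."""
    tcol = f"trend_{trend_source}"
    _check_rows(rows, extra=(tcol,))
    sub = subset_rows(rows, heterogeneity="monotone", min_khz=min_khz)
    sub = sub.dropna(subset=[tcol])
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 species for a correlation, got {n}")
    b2 = sub["beta2"].to_numpy(dtype=float)
    tr = sub[tcol].to_numpy(dtype=float)
    r, p = pearson_with_p(b2, tr)
    loo = []
    for i, sp in enumerate(sub["species"]):
        mask = np.arange(n) != i
        if n - 1 >= 3:
            r_i, p_i = pearson_with_p(b2[mask], tr[mask])
        else:
            r_i, p_i = float("nan"), float("nan")
        loo.append({"excluded": sp, "r": r_i, "p": p_i})
    return {"r": r, "p": p, "n": n, "species": sub["species"].tolist(),
            "leave_one_out": pd.DataFrame(loo)}
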