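"""BBS-style count pipeline: zero-filling, exclusion filters, per-species
overdispersed Poisson GAMMs, and pooled proportional-change curves by
vocalization group.

Filter order is fixed and auditable through :class:`FilterReport`:

1. drop records failing the single-observer / acceptable-weather flags;
2. drop each observer-route combination's first calendar year;
3. keep only observer-route runs of >= 10 consecutive surveyed years
   (a gap in coverage resets the run);
4. per species x stratum, require >= 3 distinct observers;
5. per species x stratum, drop the stratum when pooled observer ages and
   calendar year correlate more strongly than |r| = 0.7 (Pearson).

Zeros are added before filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gamm import GammConfig, GammError, PoissonGamm
from .smoothing import fit_psmooth

logger = logging.getLogger(__name__)


@dataclass
class FilterRules:
    min_series_years: int = 10
    min_observers_per_stratum: int = 3
    max_age_year_correlation: float = 0.7
    drop_first_year: bool = True
    require_flags: bool = True

    def __post_init__(self):
        if self.min_series_years <= 0 or self.min_observers_per_stratum <= 0:
            raise ValueError("rule thresholds must be positive")
        if not 0 < self.max_age_year_correlation <= 1:
            raise ValueError("correlation cutoff must lie in (0, 1]")


@dataclass
class FilterReport:
    """Per-rule record removals; removed + retained must equal the input."""

    n_input: int
    removed_flags: int = 0
    removed_first_year: int = 0
    removed_short_series: int = 0
    removed_few_observers: int = 0
    removed_confounded: int = 0
    n_retained: int = 0
    dropped_strata: dict = field(default_factory=dict)  # species -> [stratum]

    @property
    def n_removed(self) -> int:
        return (self.removed_flags + self.removed_first_year
                + self.removed_short_series + self.removed_few_observers
                + self.removed_confounded)

    def validate(self):
        if self.n_removed + self.n_retained != self.n_input:
            raise AssertionError("filter accounting does not balance")
        return self


def zero_fill(records: pd.DataFrame, species_list: list[str]) -> pd.DataFrame:
    """Add count-0 rows for every listed species absent from each surveyed
    (observer, route, year) combination. Idempotent."""
    if not species_list:
        raise ValueError("species_list must be nonempty")
    req = {"stratum", "route", "year", "observer", "species", "count"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    key = ["observer", "route", "year", "species"]
    dup = records.duplicated(subset=key, keep=False)
    if dup.any():
        dups = records.loc[dup, key].drop_duplicates().to_dict("records")
        raise ValueError(f"duplicate (observer, route, year, species) rows: {dups[:5]}")

    units = records[["stratum", "route", "year", "observer"]].drop_duplicates()
    full = units.merge(pd.DataFrame({"species": species_list}), how="cross")
    out = full.merge(records, on=["stratum", "route", "year", "observer", "species"],
                     how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    for flag in ("single_observer", "acceptable_weather"):
        if flag in records.columns:
            unit_flags = records.groupby(["observer", "route", "year"])[flag].first()
            out[flag] = out.set_index(["observer", "route", "year"]).index.map(
                unit_flags).astype(int)
    return out.sort_values(["stratum", "route", "year", "observer", "species"],
                           kind="stable").reset_index(drop=True)


def compute_min_observer_age(records: pd.DataFrame,
                             full_history: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach minimum observer age: years since the observer's first year of
    service on any route, with the first year counted as age 1.

    ``full_history`` (defaults to ``records``) supplies first-service years
    and should span the complete dataset, including years before any
    analysis window.
    """
    hist = records if full_history is None else full_history
    first = hist.groupby("observer")["year"].min()
    out = records.copy()
    out["observer_age"] = (out["year"] - out["observer"].map(first) + 1).astype(int)
    if (out["observer_age"] < 1).any():
        bad = out.loc[out["observer_age"] < 1, "observer"].unique()
        raise ValueError(
            f"records predate the observer's first appearance in the history: "
            f"{sorted(bad)[:5]}")
    return out


def _consecutive_runs(years: np.ndarray):
    """Split sorted unique years into maximal consecutive runs."""
    years = np.sort(np.unique(years))
    if years.size == 0:
        return []
    breaks = np.where(np.diff(years) > 1)[0]
    return np.split(years, breaks + 1)


def apply_filters(records: pd.DataFrame,
                  rules: FilterRules | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the five exclusion rules in order; returns data + audit report."""
    rules = rules or FilterRules()
    if "observer_age" not in records.columns:
        raise ValueError("run compute_min_observer_age before filtering")
    df = records.reset_index(drop=True)
    report = FilterReport(n_input=len(df))

    # 1. protocol flags
    if rules.require_flags:
        ok = np.ones(len(df), dtype=bool)
        for flag in ("single_observer", "acceptable_weather"):
            if flag in df.columns:
                ok &= df[flag].astype(bool).to_numpy()
        report.removed_flags = int((~ok).sum())
        df = df[ok]

    # 2. first calendar year of each observer-route combination
    if rules.drop_first_year and len(df):
        first_year = df.groupby(["observer", "route"])["year"].transform("min")
        keep = df["year"] > first_year
        report.removed_first_year = int((~keep).sum())
        df = df[keep]

    # 3. >= min_series_years consecutive surveyed years per observer-route
    if len(df):
        keep_idx = []
        for (_, _), grp in df.groupby(["observer", "route"]):
            for run in _consecutive_runs(grp["year"].to_numpy()):
                if run.size >= rules.min_series_years:
                    keep_idx.append(grp.index[grp["year"].isin(run)])
        keep = (pd.Index(np.concatenate([k.to_numpy() for k in keep_idx]))
                if keep_idx else pd.Index([], dtype=int))
        report.removed_short_series = int(len(df) - len(keep))
        df = df.loc[keep].sort_index()

    # 4. >= min observers per species x stratum
    if len(df):
        nobs = df.groupby(["species", "stratum"])["observer"].transform("nunique")
        keep = nobs >= rules.min_observers_per_stratum
        report.removed_few_observers = int((~keep).sum())
        df = df[keep]

    # 5. age-year confounding guard per species x stratum
    if len(df):
        drop_keys = []
        for (sp, st), grp in df.groupby(["species", "stratum"]):
            age = grp["observer_age"].to_numpy(dtype=float)
            year = grp["year"].to_numpy(dtype=float)
            if np.std(age) == 0 or np.std(year) == 0:
                r = 1.0  # degenerate: age carries no independent information
            else:
                r = float(np.corrcoef(age, year)[0, 1])
            if abs(r) > rules.max_age_year_correlation:
                drop_keys.append((sp, st))
                report.dropped_strata.setdefault(sp, []).append(st)
        if drop_keys:
            mask = df.set_index(["species", "stratum"]).index.isin(drop_keys)
            report.removed_confounded = int(mask.sum())
            df = df[~mask]

    report.n_retained = len(df)
    report.validate()
    return df.reset_index(drop=True), report


def fit_species_age_gamm(records: pd.DataFrame,
                         config: GammConfig | None = None) -> PoissonGamm:
    """Fit one species' overdispersed Poisson GAMM (see :mod:`.gamm`)."""
    if "species" in records.columns and records["species"].nunique() > 1:
        raise ValueError("fit one species at a time")
    return PoissonGamm(records, config)


@dataclass
class AgeEffectCurve:
    """Proportional expected count vs. observer age, relative to age 1."""

    group: str
    ages: np.ndarray
    estimate: np.ndarray  # exactly 1.0 at the first age
    lo: np.ndarray
    hi: np.ndarray
    smooth_p: float
    n_species: int
    n_records: int

    def __post_init__(self):
        if abs(self.estimate[0] - 1.0) > 1e-12:
            raise AssertionError("curve must equal 1 at the first age")
        if np.any(self.lo > self.estimate) or np.any(self.hi < self.estimate):
            raise AssertionError("pointwise band must contain the estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group, "age": self.ages,
                             "estimate": self.estimate, "lo": self.lo,
                             "hi": self.hi})


def group_proportional_curve(fits: dict[str, PoissonGamm],
                             group_of: dict[str, str],
                             ages: np.ndarray | None = None,
                             k: int = 10) -> dict[str, AgeEffectCurve]:
    """Second-stage curves: pool per-species normalized age predictions within
    each vocalization group and smooth them.

    Each species' fitted age effect is evaluated on the common age grid with
    other covariates at reference, normalized to 1 at age 1, log-transformed,
    pooled with equal species weight, and smoothed with a penalized spline.
    The returned curve is re-anchored so the value at age 1 is exactly 1.
    Groups with no species are skipped with a log entry.
    """
    groups: dict[str, list[str]] = {}
    for sp, fit in fits.items():
        g = group_of.get(sp)
        if g is None:
            logger.warning("species %s has no group assignment; skipped", sp)
            continue
        groups.setdefault(g, []).append(sp)

    curves = {}
    for g in sorted(groups):
        members = groups[g]
        if not members:
            logger.info("group %s empty; skipped", g)
            continue
        lo_age = max(min(f.age_term.xmin for f in (fits[sp] for sp in members)), 1.0)
        hi_age = min(f.age_term.xmax for f in (fits[sp] for sp in members))
        if ages is None:
            grid = np.linspace(lo_age, hi_age, 50)
        else:
            grid = np.asarray(ages, dtype=float)
            grid = grid[(grid >= lo_age) & (grid <= hi_age)]
        if grid.size < 4:
            logger.warning("group %s: age grids of member species barely overlap", g)
            continue
        xs, ys = [], []
        for sp in members:
            rel = fits[sp].proportional_age_curve(grid)
            xs.append(grid)
            ys.append(np.log(rel))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        fit2 = fit_psmooth(x, y, k=min(k, grid.size), n_grid=grid.size)
        f_grid = np.interp(grid, fit2.grid, fit2.fitted_grid)
        se_grid = np.interp(grid, fit2.grid, fit2.se_grid)
        anchor = f_grid[0]
        est = np.exp(f_grid - anchor)
        lo = np.exp(f_grid - 1.96 * se_grid - anchor)
        hi = np.exp(f_grid + 1.96 * se_grid - anchor)
        n_records = int(sum(fits[sp].n for sp in members))
        curves[g] = AgeEffectCurve(group=g, ages=grid, estimate=est, lo=lo,
                                   hi=hi, smooth_p=fit2.smooth_p,
                                   n_species=len(members), n_records=n_records)
    return curves


def run_species_pipeline(records: pd.DataFrame, species_list: list[str],
                         rules: FilterRules | None = None,
                         config: GammConfig | None = None,
                         full_history: pd.DataFrame | None = None):
    """Zero-fill, age, filter and fit every species; returns
    (fits, filter report, filtered table). Species whose GAMM cannot be fit
    (too few records, rank deficiency) are logged and skipped."""
    filled = zero_fill(records, species_list)
    aged = compute_min_observer_age(filled, full_history=full_history)
    filtered, report = apply_filters(aged, rules)
    fits = {}
    for sp, grp in filtered.groupby("species"):
        try:
            fits[sp] = fit_species_age_gamm(grp, config)
        except (GammError, ValueError) as exc:
            logger.warning("species %s: GAMM not fitted (%s)", sp, exc)
    return fits, report, filtered
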