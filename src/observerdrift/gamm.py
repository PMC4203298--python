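"""Overdispersed Poisson GAMM engine for the count-decline analysis.

log mu = intercept + f_age(observer_age) + sum_s f_s(year) * I(stratum = s)
         + u_observer

* f_age and the per-stratum year effects are centered cubic P-splines with
  second-order difference penalties (so the infinite-smoothing limit of each
  is a straight line);
* observer intercepts are a ridge-penalized indicator block, the
  mixed-model-as-penalty representation of random intercepts;
* smoothing parameters minimize a GCV criterion over the penalized IRLS fit
  (one parameter for the age smooth, one shared by the year smooths, one for
  the observer block);
* the overdispersion scale is Pearson chi-square over residual degrees of
  freedom, and the age-smooth p-value is an approximate Wald/F test on the
  penalized age coefficients at their effective degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .splines import SmoothTerm


class GammError(RuntimeError):
    pass


@dataclass
class GammConfig:
    k_age: int = 10
    k_year: int = 10
    include_year_smooths: bool = True
    include_observer_intercepts: bool = True
    max_irls_iter: int = 60
    tol: float = 1e-8
    # forced smoothing parameters; None = select by GCV. np.inf collapses a
    # smooth to its (linear / zero) null space.
    lambda_age: float | None = None
    lambda_year: float | None = None
    lambda_obs: float | None = None


class PoissonGamm:
    """A fitted overdispersed Poisson GAMM for one species."""

    def __init__(self, records: pd.DataFrame, config: GammConfig | None = None):
        cfg = config or GammConfig()
        self.config = cfg
        req = {"count", "observer_age", "year", "stratum", "observer"}
        missing = req - set(records.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        df = records.reset_index(drop=True)
        if len(df) < 30:
            raise GammError(f"need >= 30 records to fit, got {len(df)}")
        self.n = len(df)
        self.y = df["count"].to_numpy(dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("counts must be nonnegative integers")

        age = df["observer_age"].to_numpy(dtype=float)
        if np.unique(age).size < 4:
            raise GammError("too few distinct observer ages for an age smooth")
        self._build_design(df, age, cfg)
        self._fit(cfg)

    # ---- design -----------------------------------------------------------
    def _build_design(self, df, age, cfg):
        blocks = [np.ones((self.n, 1))]
        penalties = []  # (slice, S, group) with group in {age, year, obs}
        col = 1

        lam_age_inf = cfg.lambda_age is not None and np.isinf(cfg.lambda_age)
        self.age_term = SmoothTerm(age, k=cfg.k_age, linear=lam_age_inf)
        Xa = self.age_term.design(age)
        self.age_slice = slice(col, col + Xa.shape[1])
        blocks.append(Xa)
        penalties.append((self.age_slice, self.age_term.penalty, "age"))
        col += Xa.shape[1]

        self.year_terms = {}
        self.year_slices = {}
        self.strata = sorted(df["stratum"].unique())
        if cfg.include_year_smooths:
            lam_year_inf = cfg.lambda_year is not None and np.isinf(cfg.lambda_year)
            for s in self.strata:
                mask = (df["stratum"] == s).to_numpy()
                yr = df.loc[mask, "year"].to_numpy(dtype=float)
                n_years = np.unique(yr).size
                if n_years < 2:
                    raise GammError(
                        f"stratum {s!r} has a single survey year; the year "
                        "effect is rank deficient -- drop the stratum or "
                        "disable year smooths")
                if n_years < 5 or lam_year_inf:
                    term = SmoothTerm(yr, linear=True)
                else:
                    term = SmoothTerm(yr, k=min(cfg.k_year, n_years))
                Xs = np.zeros((self.n, term.ncoef))
                Xs[mask] = term.design(yr)
                sl = slice(col, col + term.ncoef)
                self.year_terms[s] = term
                self.year_slices[s] = sl
                blocks.append(Xs)
                pen = term.penalty if not term.linear else np.eye(term.ncoef) * 0.0
                penalties.append((sl, pen, "year"))
                col += term.ncoef

        self.observers = sorted(df["observer"].unique())
        self.obs_slice = None
        lam_obs_inf = cfg.lambda_obs is not None and np.isinf(cfg.lambda_obs)
        if cfg.include_observer_intercepts and not lam_obs_inf:
            codes = pd.Categorical(df["observer"], categories=self.observers).codes
            Z = np.zeros((self.n, len(self.observers)))
            Z[np.arange(self.n), codes] = 1.0
            # center so the block is orthogonal to the intercept
            Z = Z - Z.mean(axis=0, keepdims=True)
            self.obs_slice = slice(col, col + Z.shape[1])
            blocks.append(Z)
            penalties.append((self.obs_slice, np.eye(Z.shape[1]), "obs"))
            col += Z.shape[1]

        self.X = np.column_stack(blocks)
        self.p = self.X.shape[1]
        self._penalties = penalties
        # year smooths in the linear limit carry no curvature penalty but a
        # tiny ridge keeps the normal equations well conditioned
        self._ridge = 1e-9

    def _penalty_matrix(self, lam_age, lam_year, lam_obs):
        S = np.zeros((self.p, self.p))
        lam = {"age": lam_age, "year": lam_year, "obs": lam_obs}
        for sl, Sj, group in self._penalties:
            lj = lam[group]
            if lj is None or np.isinf(lj):
                lj = 0.0
            S[sl, sl] += lj * Sj
        S += self._ridge * np.eye(self.p)
        return S

    # ---- fitting ----------------------------------------------------------
    def _pirls(self, S):
        """Penalized IRLS; returns (beta, edf, deviance, converged, H_inv, XtWX)."""
        y = self.y
        X = self.X
        mu = np.maximum(y, 0.5)
        eta = np.log(mu)
        beta = None
        dev_old = np.inf
        converged = False
        for _ in range(self.config.max_irls_iter):
            w = mu
            z = eta + (y - mu) / mu
            XtW = X.T * w
            A = XtW @ X + S
            try:
                beta = np.linalg.solve(A, XtW @ z)
            except np.linalg.LinAlgError as exc:
                raise GammError(f"normal equations singular: {exc}") from exc
            eta = np.clip(X @ beta, -30, 30)
            mu = np.exp(eta)
            with np.errstate(divide="ignore", invalid="ignore"):
                dterms = np.where(y > 0, y * np.log(y / mu) - (y - mu), mu)
            dev = 2.0 * float(dterms.sum())
            if abs(dev - dev_old) < self.config.tol * (abs(dev) + 0.1):
                converged = True
                break
            dev_old = dev
        XtW = X.T * mu
        A = XtW @ X + S
        Ainv = np.linalg.inv(A)
        XtWX = XtW @ X
        edf = float(np.trace(Ainv @ XtWX))
        return beta, edf, dev, converged, Ainv, XtWX, mu

    def _fit(self, cfg):
        free = [g for g, forced in (("age", cfg.lambda_age),
                                    ("year", cfg.lambda_year),
                                    ("obs", cfg.lambda_obs))
                if forced is None and self._has_group(g)]

        def lambdas_from(x):
            lam = {"age": cfg.lambda_age, "year": cfg.lambda_year,
                   "obs": cfg.lambda_obs}
            for g, v in zip(free, x):
                lam[g] = float(np.exp(v))
            return lam

        def gcv(x):
            lam = lambdas_from(x)
            S = self._penalty_matrix(lam["age"], lam["year"], lam["obs"])
            try:
                _, edf, dev, _, _, _, _ = self._pirls(S)
            except GammError:
                return np.inf
            denom = max(self.n - edf, 1e-6) ** 2
            return self.n * dev / denom

        if free:
            # coordinate descent over a log-lambda grid; the GCV surface is
            # flat enough that derivative-free local search stalls
            grid = np.log(10.0) * np.arange(-4.0, 8.5, 1.0)
            x = np.zeros(len(free))
            for _ in range(2):
                for j in range(len(free)):
                    scores = []
                    for g in grid:
                        xj = x.copy()
                        xj[j] = g
                        scores.append(gcv(xj))
                    x[j] = grid[int(np.argmin(scores))]
            lam = lambdas_from(x)
        else:
            lam = lambdas_from([])
        self.lambdas = lam

        S = self._penalty_matrix(lam["age"], lam["year"], lam["obs"])
        beta, edf, dev, converged, Ainv, XtWX, mu = self._pirls(S)
        if not converged:
            self.converged = False
        else:
            self.converged = True
        self.beta = beta
        self.edf = edf
        self.deviance = dev
        self.mu = mu
        pearson = float(np.sum((self.y - mu) ** 2 / mu))
        self.df_resid = max(self.n - edf, 1.0)
        self.scale = pearson / self.df_resid
        # frequentist covariance of the penalized estimator, scaled for
        # overdispersion
        self.vcov = Ainv @ XtWX @ Ainv * self.scale
        self.vcov_bayes = Ainv * self.scale
        self._edf_age = float(np.trace((Ainv @ XtWX)[self.age_slice,
                                                     self.age_slice]))
        self.age_smooth_p = self._age_wald_p()

    def _has_group(self, g):
        return any(grp == g for _, _, grp in self._penalties)

    def _age_wald_p(self) -> float:
        sl = self.age_slice
        b = self.beta[sl]
        V = self.vcov_bayes[sl, sl]
        r = max(int(round(self._edf_age)), 1)
        r = min(r, b.size)
        try:
            Vi = np.linalg.pinv(V, rcond=1e-10)
        except np.linalg.LinAlgError:
            return float("nan")
        T = float(b @ Vi @ b)
        F = T / r
        return float(stats.f.sf(F, r, self.df_resid))

    # ---- prediction -------------------------------------------------------
    @property
    def age_edf(self) -> float:
        return self._edf_age

    def age_effect(self, ages) -> np.ndarray:
        """f_age evaluated at given ages (centered smooth, log scale)."""
        ages = np.asarray(ages, dtype=float)
        Xa = self.age_term.design(ages)
        return Xa @ self.beta[self.age_slice]

    def age_effect_se(self, ages) -> np.ndarray:
        Xa = self.age_term.design(np.asarray(ages, dtype=float))
        V = self.vcov_bayes[self.age_slice, self.age_slice]
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xa, V, Xa), 0.0))

    def proportional_age_curve(self, ages) -> np.ndarray:
        """exp(f_age(a) - f_age(min(a))): expected count relative to the
        youngest age supplied, other covariates held at reference."""
        f = self.age_effect(ages)
        return np.exp(f - f[0])

    def linear_coefficients(self) -> dict:
        """Intercept plus all non-observer coefficients (for oracle tests)."""
        out = {"intercept": float(self.beta[0]),
               "age": self.beta[self.age_slice].copy()}
        for s, sl in self.year_slices.items():
            out[f"year:{s}"] = self.beta[sl].copy()
        return out
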