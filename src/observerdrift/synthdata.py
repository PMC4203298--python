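"""Seeded synthetic survey data with known truth.

Three generators mirror the data the downstream analyses expect:

* ``simulate_atlas`` -- replicated detection/nondetection histories per
  10x10 km square, with observer age class, gender and effort covariates and
  a first-atlas detection flag (input to the occupancy model).
* ``simulate_bbs`` -- single-visit annual route counts with stratum-level
  population trends, observer random intercepts, a smooth observer-age
  detection decline, and overdispersion (input to the count GAMMs).
* ``synthesize_vocalization`` -- tone-stack waveforms standing in for field
  recordings (input to the vocal classifier).

A quadratic hearing-threshold-shift helper converts an (age, sex, frequency)
triple into a dB loss; it is used only to parameterize simulated age effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

AGE_CLASSES = ("under40", "mid", "over50")
GENDERS = ("female", "male")

#: Default per-sex, per-frequency quadratic coefficients a in
#: shift(age) = a * (age - 18)^2 dB. Chosen so losses rise with frequency
#: and rise faster for men than women at high frequencies; override per run.
DEFAULT_HEARING_COEFFS = {
    "male": {1.0: 0.0004, 4.0: 0.0035, 6.0: 0.0065, 8.0: 0.0105},
    "female": {1.0: 0.0004, 4.0: 0.0025, 6.0: 0.0045, 8.0: 0.0060},
}


def hearing_threshold_shift(age: float, sex: str, freq: float,
                            coeffs: dict | None = None) -> float:
    """Median expected hearing-threshold shift in dB at a test frequency.

    Quadratic in years past 18: ``a * (age - 18)**2`` with a per-sex,
    per-frequency coefficient ``a``.
    """
    if age < 18:
        raise ValueError(f"age must be >= 18, got {age}")
    table = DEFAULT_HEARING_COEFFS if coeffs is None else coeffs
    if sex not in table:
        raise ValueError(f"unknown sex {sex!r}; expected one of {sorted(table)}")
    row = table[sex]
    f = float(freq)
    if f not in row:
        raise ValueError(
            f"frequency {freq} kHz not configured; available: {sorted(row)}"
        )
    return row[f] * (age - 18.0) ** 2


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class AtlasSimConfig:
    """Parameters of the atlas detection-history generator.

    Coefficients are on the logit scale: occupancy
    ``logit(psi) = occupancy_intercept + first_atlas_coef * firstAtlas`` and
    detection
    ``logit(p) = detect_intercept + effort_coef * effort
    + age_coef * I(over50) + gender_coef * I(male)``
    (plus ``mid_age_coef * I(mid)`` for the borderline cohort).
    """

    n_squares: int = 200
    years: Sequence[int] = (2001, 2002, 2003, 2004, 2005)
    occupancy_intercept: float = 0.5
    first_atlas_coef: float = 1.0
    detect_intercept: float = 0.0
    effort_coef: float = 0.02
    age_coef: float = -1.0
    gender_coef: float = 0.2
    mid_age_coef: float | None = None  # default: half the over-50 contrast
    cohort_mix: Sequence[float] = (0.4, 0.0, 0.6)  # under40 / mid / over50
    effort_mean: float = 30.0
    effort_sd: float = 10.0
    n_observers: int = 60
    first_atlas_prob: float = 0.5
    species: str = "SYNTH1"
    seed: int = 0

    def __post_init__(self):
        if self.n_squares < 1:
            raise ValueError("n_squares must be positive")
        if len(self.years) < 2:
            raise ValueError("need at least two survey years per square")
        mix = np.asarray(self.cohort_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("cohort_mix must be 3 nonnegative proportions summing to 1")
        if self.effort_mean <= 0 or self.effort_sd < 0:
            raise ValueError("effort must be positive")
        for name in ("occupancy_intercept", "first_atlas_coef", "detect_intercept",
                     "effort_coef", "age_coef", "gender_coef"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        p_mean = _sigmoid(self.detect_intercept + self.effort_coef * self.effort_mean)
        if not 0.0 < float(p_mean) < 1.0:
            raise ValueError("implied detection probability degenerate at mean covariates")

    @property
    def mid_coef(self) -> float:
        return self.age_coef / 2.0 if self.mid_age_coef is None else self.mid_age_coef


def _lognormal_params(mean: float, sd: float):
    if sd == 0:
        return np.log(mean), 0.0
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def simulate_atlas(config: AtlasSimConfig):
    """Simulate replicated atlas detection histories.

    Returns ``(detections, observers, truth)``: a visit-level DataFrame, an
    observer covariate DataFrame, and a truth dict holding the generating
    coefficients plus the latent occupancy states.
    """
    rng = np.random.default_rng(config.seed)
    n_obs = config.n_observers
    cohorts = rng.choice(AGE_CLASSES, size=n_obs, p=np.asarray(config.cohort_mix, float))
    genders = rng.choice(GENDERS, size=n_obs)
    observers = pd.DataFrame({
        "observer": [f"obs{i:04d}" for i in range(n_obs)],
        "age_class": cohorts,
        "gender": genders,
    })

    first_atlas = rng.random(config.n_squares) < config.first_atlas_prob
    psi = _sigmoid(config.occupancy_intercept
                   + config.first_atlas_coef * first_atlas.astype(float))
    z = rng.random(config.n_squares) < psi

    years = list(config.years)
    n_visits = config.n_squares * len(years)
    sq_idx = np.repeat(np.arange(config.n_squares), len(years))
    year_col = np.tile(years, config.n_squares)
    obs_idx = rng.integers(0, n_obs, size=n_visits)
    mu, sg = _lognormal_params(config.effort_mean, config.effort_sd)
    effort = rng.lognormal(mu, sg, size=n_visits)

    age_cl = cohorts[obs_idx]
    logit_p = (config.detect_intercept
               + config.effort_coef * effort
               + config.age_coef * (age_cl == "over50")
               + config.mid_coef * (age_cl == "mid")
               + config.gender_coef * (genders[obs_idx] == "male"))
    p = _sigmoid(logit_p)
    detected = (rng.random(n_visits) < p) & z[sq_idx]

    detections = pd.DataFrame({
        "square": [f"sq{i:05d}" for i in sq_idx],
        "year": year_col,
        "observer": observers["observer"].to_numpy()[obs_idx],
        "age_class": age_cl,
        "gender": genders[obs_idx],
        "effort": effort,
        "species": config.species,
        "detected": detected.astype(int),
        "first_atlas_detected": first_atlas[sq_idx].astype(int),
    })
    truth = {
        "occupancy_intercept": config.occupancy_intercept,
        "first_atlas_coef": config.first_atlas_coef,
        "detect_intercept": config.detect_intercept,
        "effort_coef": config.effort_coef,
        "age_coef": config.age_coef,
        "gender_coef": config.gender_coef,
        "mid_age_coef": config.mid_coef,
        "z": z.astype(int).tolist(),
        "psi": psi.tolist(),
    }
    return detections, observers, truth


@dataclass
class BbsSimConfig:
    """Parameters of the BBS-style count generator.

    ``stratum_trend_fn(stratum_index, year)`` and ``age_decline_fn(age)`` act
    on the log scale; ``age_decline_fn(1)`` must be 0 so the first year of
    service is the baseline. ``overdispersion`` is the target
    variance-to-mean ratio of the counts (1 = pure Poisson).
    """

    n_strata: int = 2
    routes_per_stratum: int = 5
    year_range: tuple[int, int] = (1970, 2007)
    tenure_mean: float = 10.0
    baseline_log_mean: float = 1.5
    route_sd: float = 0.0
    stratum_trend_fn: Callable[[int, int], float] = field(
        default=lambda s, year: 0.0)
    age_decline_fn: Callable[[float], float] = field(default=lambda age: 0.0)
    observer_sd: float = 0.0
    overdispersion: float = 1.0
    species: str = "SYNTH1"
    seed: int = 0

    def __post_init__(self):
        if self.n_strata < 1 or self.routes_per_stratum < 1:
            raise ValueError("need at least one stratum and route")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ValueError("year_range must be increasing")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion multiplier must be >= 1")
        if self.tenure_mean < 1:
            raise ValueError("tenure_mean must be >= 1")
        if abs(self.age_decline_fn(1)) > 1e-12:
            raise ValueError("age_decline_fn(1) must be 0 (first-year baseline)")
        if self.observer_sd < 0 or self.route_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def simulate_bbs(config: BbsSimConfig):
    """Simulate single-visit annual BBS-style counts.

    Each route is covered by a sequence of observers with geometric-ish
    tenure lengths; an observer's first year on the route is their first
    year of service anywhere, so minimum observer age is recoverable from
    the table alone. Returns ``(counts, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    years = np.arange(y0, y1 + 1)
    rows = []
    observer_counter = 0
    route_baselines = {}
    observer_first = {}
    obs_intercepts = {}

    for s in range(config.n_strata):
        stratum = f"S{s:02d}"
        for r in range(config.routes_per_stratum):
            route = f"{stratum}-R{r:03d}"
            base = config.baseline_log_mean + (
                rng.normal(0.0, config.route_sd) if config.route_sd > 0 else 0.0)
            route_baselines[route] = base
            yi = 0
            while yi < years.size:
                tenure = max(1, int(rng.geometric(1.0 / config.tenure_mean)))
                obs = f"bbs{observer_counter:05d}"
                observer_counter += 1
                first_year = int(years[yi])
                observer_first[obs] = first_year
                u = rng.normal(0.0, config.observer_sd) if config.observer_sd > 0 else 0.0
                obs_intercepts[obs] = u
                for t in range(tenure):
                    if yi + t >= years.size:
                        break
                    year = int(years[yi + t])
                    age = year - first_year + 1
                    log_mu = (base + config.stratum_trend_fn(s, year)
                              + u + config.age_decline_fn(age))
                    rows.append((stratum, route, year, obs, age, log_mu))
                yi += tenure

    df = pd.DataFrame(rows, columns=["stratum", "route", "year", "observer",
                                     "true_age", "log_mu"])
    mu = np.exp(df["log_mu"].to_numpy())
    v = config.overdispersion
    if v > 1.0:
        # per-record gamma multiplier with variance (v-1)/mu: gives counts
        # with variance/mean ratio v at every mu (quasi-Poisson)
        pos = mu > 0
        g = np.ones_like(mu)
        shape = np.where(pos, mu / (v - 1.0), 1.0)
        g[pos] = rng.gamma(shape[pos], (v - 1.0) / np.maximum(mu[pos], 1e-300))
        mu = mu * g
    counts = np.zeros(mu.size, dtype=int)
    pos = mu > 0
    counts[pos] = rng.poisson(mu[pos])

    out = df[["stratum", "route", "year", "observer"]].copy()
    out["species"] = config.species
    out["count"] = counts
    out["single_observer"] = 1
    out["acceptable_weather"] = 1
    truth = {
        "baseline_log_mean": config.baseline_log_mean,
        "route_baselines": route_baselines,
        "observer_first_year": observer_first,
        "observer_intercepts": obs_intercepts,
        "overdispersion": config.overdispersion,
    }
    return out, truth


@dataclass
class VocalSpec:
    """Recipe for a synthetic vocalization waveform.

    ``components`` is a list of (frequency_khz, relative_amplitude[,
    sweep_end_khz]) tuples; a third element makes the tone a linear sweep.
    """

    sample_rate: int = 44100
    duration: float = 1.0
    components: Sequence[tuple] = ((4.0, 1.0),)
    noise_floor: float = 0.0

    def __post_init__(self):
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        if not self.components:
            raise ValueError("need at least one component")
        nyq = self.sample_rate / 2000.0  # kHz
        amps = []
        for comp in self.components:
            f, a = comp[0], comp[1]
            fe = comp[2] if len(comp) > 2 else f
            if f >= nyq or fe >= nyq:
                raise ValueError(
                    f"component frequency {max(f, fe)} kHz >= Nyquist {nyq} kHz")
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
            amps.append(a)
        if max(amps) <= 0:
            raise ValueError("at least one component amplitude must be positive")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")


def synthesize_vocalization(spec: VocalSpec, seed: int = 0):
    """Render a tone stack (with optional linear sweeps) plus white noise.

    Returns ``(samples, sample_rate)`` with samples as float64 in [-1, 1]
    scale before normalization (peak-normalized to 0.9).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.sample_rate * spec.duration))
    t = np.arange(n) / spec.sample_rate
    x = np.zeros(n)
    for comp in spec.components:
        f0 = comp[0] * 1000.0
        a = comp[1]
        f1 = (comp[2] * 1000.0) if len(comp) > 2 else f0
        # linear sweep: instantaneous frequency f0 -> f1 over the duration
        phase = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * spec.duration))
        x += a * np.sin(phase)
    if spec.noise_floor > 0:
        x += spec.noise_floor * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return x, spec.sample_rate


def write_wav(path, samples, rate: int) -> None:
    """Write a mono 16-bit PCM WAV file."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(rate), (x * 32767).astype(np.int16))


def read_wav(path):
    """Read a PCM WAV file; stereo is averaged to mono. Returns (samples, rate)."""
    rate, data = wavfile.read(str(path))
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        x = x / np.iinfo(np.asarray(data).dtype).max
    return x, int(rate)


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
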