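"""Typed table I/O, run configuration and full-pipeline orchestration.

A run is a single JSON config document; every stage derives its own seed
from the master seed and the stage name, so stages are independently
reproducible. The manifest records the config hash, stage seeds, row counts
and output-file digests; re-running an identical config reproduces identical
digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bbscounts, linkage, occupancy, synthdata, vocal

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "occupancy", "bbs", "linkage")

# ---------------------------------------------------------------------------
# table schemas
# ---------------------------------------------------------------------------

SCHEMAS: dict[str, dict[str, type]] = {
    "detections": {
        "square": str, "year": int, "observer": str, "age_class": str,
        "gender": str, "effort": float, "species": str, "detected": int,
        "first_atlas_detected": int,
    },
    "counts": {
        "stratum": str, "route": str, "year": int, "observer": str,
        "species": str, "count": int, "single_observer": int,
        "acceptable_weather": int,
    },
    "vocal_classes": {
        "species": str, "peak_khz": float, "sd": float, "heterogeneity": str,
        "freq_group": str, "group8": str,
    },
    "species_effects": {
        "species": str, "peak_khz": float, "heterogeneity": str,
        "beta2": float, "beta2_var": float, "trend_a": float,
        "trend_a_ci_width": float, "trend_b": float, "trend_b_routes": float,
    },
    "curves": {
        "group": str, "age": float, "estimate": float, "lo": float, "hi": float,
    },
}


class TableError(ValueError):
    pass


def _coerce_column(series: pd.Series, name: str, typ: type) -> pd.Series:
    if typ is str:
        return series.astype(str)
    if typ is float:
        try:
            return pd.to_numeric(series, errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise TableError(f"column {name!r}: non-numeric value ({exc})") from exc
    if typ is int:
        num = pd.to_numeric(series, errors="coerce")
        bad = num.isna() | (num != np.floor(num))
        if bad.any():
            row = int(bad.idxmax())
            raise TableError(
                f"column {name!r}, row {row}: value {series.iloc[row]!r} is not "
                "an integer")
        return num.astype(int)
    raise TableError(f"unsupported schema type for column {name!r}")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV with strict typed parsing against a registered schema."""
    if schema not in SCHEMAS:
        raise TableError(f"unknown schema {schema!r}; registered: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec if c not in df.columns]
    extra = [c for c in df.columns if c not in spec]
    if missing:
        raise TableError(f"{path}: missing columns {missing}")
    if extra:
        raise TableError(f"{path}: unexpected columns {extra}")
    out = pd.DataFrame(index=df.index)
    for name, typ in spec.items():
        out[name] = _coerce_column(df[name], name, typ)
    return out


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a CSV in schema column order (round-trips through read_table)."""
    if schema not in SCHEMAS:
        raise TableError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise TableError(f"cannot write {schema}: missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[list(spec)].to_csv(path, index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def stage_seed(master_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class Thresholds:
    """Analysis rule constants (defaults are the published rule values)."""

    freq_thresholds_khz: tuple = (3.0, 6.0, 7.0)
    max_age_year_correlation: float = 0.7
    min_series_years: int = 10
    min_observers_per_stratum: int = 3
    age_young_max: int = 40
    age_old_min: int = 50
    min_detections: int = 100
    interval_level: float = 0.95


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    master_seed: int = 0
    stages: tuple = STAGES
    n_species: int = 8
    thresholds: Thresholds = field(default_factory=Thresholds)
    atlas: dict = field(default_factory=dict)       # AtlasSimConfig overrides
    bbs: dict = field(default_factory=dict)         # BbsSimConfig overrides
    occupancy: dict = field(default_factory=dict)   # OccuModelSpec overrides
    filters: dict = field(default_factory=dict)     # FilterRules overrides
    trend_source: str = "a"

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if self.trend_source not in ("a", "b", "mean"):
            raise ValueError("trend_source must be 'a', 'b' or 'mean'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            tknown = {f.name for f in dataclasses.fields(Thresholds)}
            tunknown = set(d["thresholds"]) - tknown
            if tunknown:
                raise ValueError(f"unknown threshold keys: {sorted(tunknown)}")
            t = d["thresholds"]
            if "freq_thresholds_khz" in t:
                t["freq_thresholds_khz"] = tuple(t["freq_thresholds_khz"])
            d["thresholds"] = Thresholds(**t)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["thresholds"]["freq_thresholds_khz"] = list(
            self.thresholds.freq_thresholds_khz)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    stages_run: list
    row_counts: dict
    digests: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


class StageFailure(RuntimeError):
    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_manifest = manifest
        self.cause = cause


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _species_roster(n_species: int, rng: np.random.Generator):
    """Assign each synthetic species a peak frequency across 2-8.5 kHz, an
    alternating monotone/heterogeneous song structure, and an age effect that
    grows with the hearing-threshold shift at its nearest test frequency."""
    freqs = np.linspace(2.0, 8.5, n_species)
    roster = []
    test_freqs = np.array([1.0, 4.0, 6.0, 8.0])
    for i, f in enumerate(freqs):
        name = f"SP{i:02d}"
        hetero = i % 2 == 1
        if hetero:
            comps = [(max(0.3, f + d), 1.0 / (1 + abs(j - 4)))
                     for j, d in enumerate(np.linspace(-1.5, 1.5, 9))]
            # keep the nominal peak dominant
            comps[4] = (f, 2.0)
        else:
            comps = [(f, 1.0)]
        near = float(test_freqs[np.argmin(np.abs(test_freqs - f))])
        shift = synthdata.hearing_threshold_shift(60, "male", near)
        age_coef = -shift / 18.0  # ~ -1 logit at 8 kHz by age 60
        roster.append({"species": name, "peak_khz": float(f), "hetero": hetero,
                       "components": comps, "age_coef": float(age_coef)})
    return roster


def run_all(config: RunConfig, log_level: str = "INFO") -> RunManifest:
    """Execute the enabled stages in order and write a manifest.

    simulate -> classify -> fit-occupancy -> run-bbs -> link-trends. A stage
    failure aborts the run with the stage name and the partial manifest.
    """
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.master_seed, s) for s in STAGES}
    manifest = RunManifest(config_hash=config.config_hash(), seeds=seeds,
                           stages_run=[], row_counts={}, digests={})
    rng = np.random.default_rng(seeds["simulate"])
    roster = _species_roster(config.n_species, rng)

    def record(stage, name, path):
        manifest.digests[f"{stage}/{name}"] = file_digest(path)

    try:
        if "simulate" in config.stages:
            det_frames, cnt_frames = [], []
            wav_dir = out / "audio"
            wav_dir.mkdir(exist_ok=True)
            for j, sp in enumerate(roster):
                acfg = synthdata.AtlasSimConfig(
                    species=sp["species"], age_coef=sp["age_coef"],
                    seed=seeds["simulate"] + 17 * j, **config.atlas)
                det, _, _ = synthdata.simulate_atlas(acfg)
                det_frames.append(det)
                coef = sp["age_coef"]
                bcfg = synthdata.BbsSimConfig(
                    species=sp["species"],
                    age_decline_fn=lambda a, c=coef: c * (a - 1) / 30.0,
                    seed=seeds["simulate"] + 31 * j, **config.bbs)
                cnt, _ = synthdata.simulate_bbs(bcfg)
                cnt_frames.append(cnt)
                spec = synthdata.VocalSpec(components=sp["components"],
                                           noise_floor=0.01)
                wave, rate = synthdata.synthesize_vocalization(
                    spec, seed=seeds["simulate"] + 7 * j)
                synthdata.write_wav(wav_dir / f"{sp['species']}.wav", wave, rate)
            detections = pd.concat(det_frames, ignore_index=True)
            counts = pd.concat(cnt_frames, ignore_index=True)
            write_table(detections, out / "detections.csv", "detections")
            write_table(counts, out / "counts.csv", "counts")
            manifest.row_counts["simulate/detections"] = len(detections)
            manifest.row_counts["simulate/counts"] = len(counts)
            record("simulate", "detections", out / "detections.csv")
            record("simulate", "counts", out / "counts.csv")
            manifest.stages_run.append("simulate")

        if "classify" in config.stages:
            classes = vocal.classify_wav_dir(out / "audio")
            write_table(classes, out / "vocal_classes.csv", "vocal_classes")
            manifest.row_counts["classify/vocal_classes"] = len(classes)
            record("classify", "vocal_classes", out / "vocal_classes.csv")
            manifest.stages_run.append("classify")

        if "occupancy" in config.stages:
            detections = read_table(out / "detections.csv", "detections")
            spec = occupancy.OccuModelSpec(seed=seeds["occupancy"],
                                           **config.occupancy)
            rows = []
            for sp_name, grp in detections.groupby("species"):
                fit = occupancy.fit_occupancy_mcmc(grp, spec)
                if not fit.converged:
                    logger.warning("species %s: occupancy fit not converged",
                                   sp_name)
                b2 = occupancy.extract_beta2(fit, force=True)
                rows.append({"species": sp_name, "beta2": b2["estimate"],
                             "beta2_var": b2["variance"],
                             "significant_negative": b2["significant_negative"],
                             "converged": fit.converged})
            occ_df = pd.DataFrame(rows)
            occ_df.to_csv(out / "beta2.csv", index=False)
            manifest.row_counts["occupancy/beta2"] = len(occ_df)
            record("occupancy", "beta2", out / "beta2.csv")
            manifest.stages_run.append("occupancy")

        if "bbs" in config.stages:
            counts = read_table(out / "counts.csv", "counts")
            classes = read_table(out / "vocal_classes.csv", "vocal_classes")
            rules = bbscounts.FilterRules(**config.filters)
            species_list = sorted(counts["species"].unique())
            fits, report, _ = bbscounts.run_species_pipeline(
                counts, species_list, rules=rules)
            group_of = dict(zip(classes["species"], classes["group8"]))
            curves = bbscounts.group_proportional_curve(fits, group_of)
            if curves:
                cdf = pd.concat([c.to_frame() for c in curves.values()],
                                ignore_index=True)
                write_table(cdf, out / "curves.csv", "curves")
                record("bbs", "curves", out / "curves.csv")
                manifest.row_counts["bbs/curves"] = len(cdf)
            manifest.row_counts["bbs/retained"] = report.n_retained
            (out / "filter_report.json").write_text(
                json.dumps(dataclasses.asdict(report), indent=2))
            record("bbs", "filter_report", out / "filter_report.json")
            manifest.stages_run.append("bbs")

        if "linkage" in config.stages:
            classes = read_table(out / "vocal_classes.csv", "vocal_classes")
            occ_df = pd.read_csv(out / "beta2.csv")
            rng2 = np.random.default_rng(seeds["linkage"])
            table = classes.merge(occ_df[["species", "beta2", "beta2_var"]],
                                  on="species")
            # synthetic exogenous trends: decline proportional to the age
            # effect plus noise (the real tables are agency inputs)
            table["trend_a"] = 2.0 * table["beta2"] + 0.3 * rng2.standard_normal(len(table))
            table["trend_a_ci_width"] = rng2.uniform(0.5, 2.0, len(table))
            table["trend_b"] = 2.0 * table["beta2"] + 0.3 * rng2.standard_normal(len(table))
            table["trend_b_routes"] = rng2.integers(10, 200, len(table)).astype(float)
            write_table(table, out / "species_effects.csv", "species_effects")
            record("linkage", "species_effects", out / "species_effects.csv")
            results = {}
            for het in ("monotone", "heterogeneous"):
                try:
                    f = linkage.fit_beta2_vs_frequency(table, subset=het)
                    results[f"beta2_smooth_{het}"] = {
                        "intercept": f.intercept, "intercept_p": f.intercept_p,
                        "smooth_p": f.smooth_p, "n": f.n}
                except ValueError as exc:
                    logger.info("beta2 smooth (%s) skipped: %s", het, exc)
            try:
                ph = linkage.posthoc_highfreq_linear(table)
                results["posthoc_highfreq"] = {
                    "slope": ph["slope"], "p": ph["slope_p"], "n": ph["n"]}
            except ValueError as exc:
                logger.info("post-hoc linear model skipped: %s", exc)
            for src in ("a", "b"):
                try:
                    corr = linkage.correlate_beta2_trend(table, trend_source=src)
                    results[f"correlation_{src}"] = {
                        "r": corr["r"], "p": corr["p"], "n": corr["n"]}
                except ValueError as exc:
                    logger.info("correlation (%s) skipped: %s", src, exc)
            (out / "linkage.json").write_text(json.dumps(results, indent=2))
            record("linkage", "results", out / "linkage.json")
            manifest.row_counts["linkage/species"] = len(table)
            manifest.stages_run.append("linkage")
    except Exception as exc:
        failed = next((s for s in config.stages
                       if s not in manifest.stages_run), "unknown")
        manifest.write(out / "manifest.partial.json")
        raise StageFailure(failed, manifest, exc) from exc

    manifest.write(out / "manifest.json")
    return manifest
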