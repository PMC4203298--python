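# observerdrift

Tools for studying observer-aging effects in long-term volunteer bird
surveys, exercised end to end on seeded synthetic data with known truth.

The pipeline has five analysis stages plus orchestration:

| module | what it does |
| --- | --- |
| `observerdrift.synthdata` | Seeded generators: atlas-style replicated detection histories (Bernoulli occupancy, logistic detection with effort/age/gender terms), BBS-style single-visit annual counts (stratum trends, observer intercepts, smooth age-related decline, overdispersion), tone-stack vocal waveforms, and a quadratic hearing-threshold-shift helper used to parameterize simulated age effects. |
| `observerdrift.vocal` | Power spectra (averaged modified periodogram), peak (dominant) frequency, spectral-spread statistic, and classification of species into eight groups: frequency bins low < 3 kHz, notch [3, 6), medium [6, 7), high >= 7 kHz, crossed with a monotone/heterogeneous median split. |
| `observerdrift.occupancy` | Two-part hierarchical occupancy/detection model with the latent state marginalized exactly; adaptive random-walk Metropolis posterior sampling; extraction of the observer-age contrast `b2` (logit-scale difference in detection between observers over 50 and under 40) with convergence diagnostics, plus the mid-age sensitivity refit. |
| `observerdrift.bbscounts` | Zero-filling, minimum observer age, the five ordered exclusion filters (protocol flags, first-year drop, 10-consecutive-year series, 3 observers per stratum, 0.7 age-year correlation guard) with an auditable `FilterReport`; per-species overdispersed Poisson GAMMs (penalized IRLS on P-splines, GCV-selected smoothing, observer ridge intercepts); pooled proportional-change curves per vocalization group, anchored to 1 at age 1. |
| `observerdrift.linkage` | Inverse-variance-weighted spline smooths of `b2` on peak frequency, the post-hoc weighted linear model for monotone species at >= 6 kHz, weighted trend-vs-frequency smooths, and Pearson correlations with leave-one-out sensitivity. |
| `observerdrift.interface` | Strict typed CSV schemas, a single-JSON run configuration (all rule thresholds default to the published values), per-stage seed derivation, and a manifest with reproducible digests. |

## CLI

```bash
observer-drift simulate atlas --config atlas.json --seed 1 --out data/
observer-drift simulate bbs   --config bbs.json   --seed 1 --out data/
observer-drift simulate vocal --config song.json  --seed 1 --out data/
observer-drift classify-vocal --in data/audio --out classes.csv
observer-drift fit-occupancy --detections data/detections.csv \
    --species all --seed 1 --out beta2.csv
observer-drift run-bbs --counts data/counts.csv \
    --species-groups classes.csv --out bbs_out/
observer-drift link-trends --table species_effects.csv --source a --out link/
observer-drift run-all --config run.json
```

Exit codes: 0 success, 2 validation error, 3 convergence failure. `run-all`
executes simulate -> classify -> fit-occupancy -> run-bbs -> link-trends
(stage toggles in the config) and writes `manifest.json`; identical
config + seed reproduces identical file digests.

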