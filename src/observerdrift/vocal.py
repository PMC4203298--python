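"""Vocalization classification by peak frequency and spectral heterogeneity.

Species are binned by the frequency of the global power-spectrum maximum
("peak frequency") using half-open thresholds at 3, 6 and 7 kHz, and split
into monotone vs. heterogeneous by comparing each spectrum's standard
deviation of (normalized) power values to the cohort median. The cross of
the four frequency bins with the two heterogeneity labels yields eight
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .synthdata import read_wav

logger = logging.getLogger(__name__)

#: Frequency-bin thresholds in kHz: low < 3, 3 <= notch < 6, 6 <= medium < 7,
#: high >= 7.
FREQ_THRESHOLDS_KHZ = (3.0, 6.0, 7.0)

FREQ_GROUPS = ("low", "notch", "medium", "high")
HETEROGENEITY = ("monotone", "heterogeneous")


@dataclass
class SpectrumParams:
    """Averaged-periodogram settings (Hann window, 50% overlap by default)."""

    nperseg: int = 4096
    overlap: float = 0.5
    window: str = "hann"
    nfft: int | None = None

    def __post_init__(self):
        if self.nperseg < 8:
            raise ValueError("nperseg too small")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a kHz grid."""

    frequencies: np.ndarray  # kHz, strictly increasing
    power: np.ndarray
    params: SpectrumParams = field(default_factory=SpectrumParams)

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("frequency and power arrays must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be nonnegative")
        self.frequencies = f
        self.power = p


def compute_power_spectrum(waveform, rate: int,
                           params: SpectrumParams | None = None) -> PowerSpectrum:
    """Averaged modified periodogram of a mono waveform.

    Raises if the waveform is shorter than one analysis segment.
    """
    params = params or SpectrumParams()
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be one-dimensional (mono)")
    if x.size < params.nperseg:
        raise ValueError(
            f"waveform has {x.size} samples; minimum is nperseg={params.nperseg}")
    noverlap = int(params.nperseg * params.overlap)
    freqs, psd = signal.welch(x, fs=rate, window=params.window,
                              nperseg=params.nperseg, noverlap=noverlap,
                              nfft=params.nfft)
    return PowerSpectrum(frequencies=freqs / 1000.0, power=psd, params=params)


def peak_frequency(spectrum: PowerSpectrum) -> float:
    """Frequency (kHz) of the global power maximum; ties go to the lowest."""
    p = spectrum.power
    if not np.any(p > 0):
        raise ValueError("degenerate spectrum: all power values are zero")
    return float(spectrum.frequencies[int(np.argmax(p))])


def spectrum_sd(spectrum: PowerSpectrum, db_scale: bool = False) -> float:
    """Standard deviation of power values across frequency bins.

    Linear power is first normalized to unit total so the statistic is
    invariant to overall amplitude; ``db_scale`` instead computes the SD of
    dB values (10*log10 of normalized power, floored at -120 dB).
    """
    p = np.asarray(spectrum.power, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all power values are zero")
    p = p / total
    if db_scale:
        p = 10.0 * np.log10(np.maximum(p, 1e-12))
    return float(np.std(p, ddof=1))


def classify_heterogeneity(sds: dict[str, float] | pd.Series) -> dict[str, str]:
    """Median-split: monotone iff a species' SD <= median over the cohort."""
    s = pd.Series(sds, dtype=float)
    if s.empty:
        raise ValueError("no spectrum SDs supplied")
    if len(s) < 2:
        raise ValueError("need at least two species for a median split")
    med = float(s.median())
    return {sp: ("monotone" if v <= med else "heterogeneous") for sp, v in s.items()}


def assign_frequency_group(peak_khz: float) -> str:
    """Half-open bins: low < 3, notch in [3, 6), medium in [6, 7), high >= 7."""
    if not peak_khz > 0:
        raise ValueError(f"peak frequency must be positive, got {peak_khz}")
    t1, t2, t3 = FREQ_THRESHOLDS_KHZ
    if peak_khz < t1:
        return "low"
    if peak_khz < t2:
        return "notch"
    if peak_khz < t3:
        return "medium"
    return "high"


def group8_label(freq_group: str, heterogeneity: str) -> str:
    return f"{freq_group.capitalize()} {heterogeneity.capitalize()}"


def _normalized(spectrum: PowerSpectrum) -> np.ndarray:
    total = spectrum.power.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all power values are zero")
    return spectrum.power / total


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Mean of unit-total-normalized spectra (per-species pooling rule)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != grid.shape or not np.allclose(s.frequencies, grid):
            raise ValueError("spectra must share a common frequency grid")
    pooled = np.mean([_normalized(s) for s in spectra], axis=0)
    return PowerSpectrum(frequencies=grid, power=pooled, params=spectra[0].params)


def classify_species_set(spectra_by_species: dict[str, list[PowerSpectrum]],
                         db_scale: bool = True) -> pd.DataFrame:
    """Classify a cohort of species into the eight vocalization groups.

    Multiple spectra per species are averaged (after normalization) before
    the peak and SD are computed; the monotone/heterogeneous split uses the
    median SD over the supplied cohort. Rows are returned in sorted species
    order so input ordering cannot influence the labels.

    The split defaults to the dB-scale SD: on the linear scale a narrow-band
    (single-pitch) song concentrates its power in few bins and gets the
    *larger* SD, inverting the intended narrow-band = monotone semantics,
    whereas in dB a lone spectral spike over a flat floor yields a small SD
    and a many-note song a large one. ``db_scale=False`` uses the linear
    normalized statistic instead.
    """
    if len(spectra_by_species) < 2:
        raise ValueError("need at least two species to classify")
    rows = {}
    for sp in sorted(spectra_by_species):
        pooled = average_spectra(list(spectra_by_species[sp]))
        rows[sp] = {
            "peak_khz": peak_frequency(pooled),
            "sd": spectrum_sd(pooled, db_scale=db_scale),
        }
    het = classify_heterogeneity({sp: r["sd"] for sp, r in rows.items()})
    out = []
    for sp, r in rows.items():
        fg = assign_frequency_group(r["peak_khz"])
        out.append({
            "species": sp, "peak_khz": r["peak_khz"], "sd": r["sd"],
            "heterogeneity": het[sp], "freq_group": fg,
            "group8": group8_label(fg, het[sp]),
        })
    return pd.DataFrame(out)


def classify_wav_dir(directory, params: SpectrumParams | None = None,
                     db_scale: bool = True) -> pd.DataFrame:
    """Classify every readable ``<species>.wav`` (or ``<species>__k.wav``) in a
    directory; unreadable files are logged and skipped."""
    directory = Path(directory)
    spectra: dict[str, list[PowerSpectrum]] = {}
    for path in sorted(directory.glob("*.wav")):
        species = path.stem.split("__")[0]
        try:
            x, rate = read_wav(path)
            spec = compute_power_spectrum(x, rate, params)
        except Exception as exc:  # per-file failure must not kill the run
            logger.warning("skipping unreadable audio file %s: %s", path, exc)
            continue
        spectra.setdefault(species, []).append(spec)
    if len(spectra) < 2:
        raise ValueError("fewer than two species with readable audio")
    return classify_species_set(spectra, db_scale=db_scale)
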