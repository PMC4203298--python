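import numpy as np
import pandas as pd
import pytest

from observerdrift import synthdata as sd
from observerdrift import vocal as vc
from observerdrift.occupancy import DetectionData


def make_detection_df(squares):
    """Build a detection DataFrame from [(first_atlas, [(y, effort, over50,
    male), ...]), ...] with one distinct year per visit."""
    rows = []
    for i, (fa, visits) in enumerate(squares):
        for k, (y, eff, over, male) in enumerate(visits):
            rows.append({
                "square": f"sq{i}", "year": 2001 + k, "observer": f"o{i}_{k}",
                "age_class": "over50" if over else "under40",
                "gender": "male" if male else "female",
                "effort": eff, "species": "X", "detected": int(y),
                "first_atlas_detected": int(fa),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def simple_square_data():
    """One square, first_atlas=0, all covariates zero -> psi = p = 0.5 at
    zero parameters. Effort must be positive in the table; pass raw effort
    through unstandardized so a 0-coefficient leaves p untouched."""
    def build(history):
        df = make_detection_df([(0, [(y, 1.0, 0, 0) for y in history])])
        return DetectionData(df, standardize_effort=False)
    return build


@pytest.fixture
def four_species_spectra():
    """Two pure tones and two 10-tone stacks (the classification fixture)."""
    specs = {
        "pure2": sd.VocalSpec(components=[(2.0, 1.0)]),
        "pure8": sd.VocalSpec(components=[(8.0, 1.0)]),
        "stack4": sd.VocalSpec(
            components=[(4.0 + d, 1.0) for d in np.linspace(-1.2, 1.2, 10)]),
        "stack65": sd.VocalSpec(
            components=[(6.5 + d, 1.0) for d in np.linspace(-0.4, 0.4, 10)]),
    }
    out = {}
    for name, spec in specs.items():
        wave, rate = sd.synthesize_vocalization(spec, seed=1)
        out[name] = [vc.compute_power_spectrum(wave, rate)]
    return out


@pytest.fixture
def bbs_filter_fixture():
    """Five observer-route series plus a two-observer stratum, for exact
    hand-enumeration of the filter rules (84 input rows):

    * A (S1/R1): 12 consecutive years 1980-1991
    * B (S1/R2): 12 years with one gap (1980-1985, 1987-1992)
    * C (S1/R3): 9 consecutive years 1980-1988
    * D (S1/R4): 15 consecutive years 1975-1989
    * G (S1/R5): 12 consecutive years 1984-1995
    * E, F (S2): 12 consecutive years 1980-1991 each

    Hand enumeration: rule 2 drops one first year per series (7 rows);
    rule 3 then drops B entirely (post-drop runs of 5 and 6) and C (run of
    8): 19 rows; rule 4 drops the two-observer stratum S2 (11 + 11 = 22
    rows); rule 5 keeps S1 (pooled age-year Pearson r = 0.619 <= 0.7).
    Retained: A 11 + D 14 + G 11 = 36 rows.
    """
    rows = []

    def series(obs, route, stratum, years):
        for y in years:
            rows.append({"stratum": stratum, "route": route, "year": y,
                         "observer": obs, "species": "X", "count": 1,
                         "single_observer": 1, "acceptable_weather": 1})

    series("A", "R1", "S1", range(1980, 1992))                      # 12
    series("B", "R2", "S1", [*range(1980, 1986), *range(1987, 1993)])  # 12, gap
    series("C", "R3", "S1", range(1980, 1989))                      # 9
    series("D", "R4", "S1", range(1975, 1990))                      # 15
    series("G", "R5", "S1", range(1984, 1996))                      # 12
    series("E", "R6", "S2", range(1980, 1992))                      # 12
    series("F", "R7", "S2", range(1980, 1992))                      # 12
    return pd.DataFrame(rows)
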