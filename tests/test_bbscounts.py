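import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from observerdrift import bbscounts as bc
from observerdrift import synthdata as sd
from observerdrift.gamm import GammConfig, GammError, PoissonGamm


def count_rows(rows):
    cols = ["stratum", "route", "year", "observer", "species", "count",
            "single_observer", "acceptable_weather"]
    return pd.DataFrame(rows, columns=cols)


class TestZeroFill:
    def test_small_counting_example(self):
        rows = [
            ("S1", "R1", 2000, "o1", "spA", 2, 1, 1),
            ("S1", "R1", 2000, "o1", "spB", 1, 1, 1),
            ("S1", "R1", 2001, "o1", "spA", 3, 1, 1),
            ("S1", "R1", 2001, "o1", "spC", 1, 1, 1),
        ]
        out = bc.zero_fill(count_rows(rows), ["spA", "spB", "spC"])
        assert len(out) == 6  # 2 route-years x 3 species
        zeros = out[out["count"] == 0]
        assert set(zip(zeros["year"], zeros["species"])) == {(2000, "spC"),
                                                            (2001, "spB")}

    def test_idempotent(self):
        rows = [("S1", "R1", 2000, "o1", "spA", 2, 1, 1)]
        once = bc.zero_fill(count_rows(rows), ["spA", "spB"])
        twice = bc.zero_fill(once, ["spA", "spB"])
        pd.testing.assert_frame_equal(once, twice)

    def test_counting_oracle_on_random_fixture(self):
        # 50 route-years x 20 species; keep a random 613 of the 1000 cells
        rng = np.random.default_rng(0)
        species = [f"sp{i:02d}" for i in range(20)]
        cells = [(f"S{ry % 5}", f"R{ry}", 1990 + ry % 10, f"o{ry}", sp)
                 for ry in range(50) for sp in species]
        keep = rng.choice(len(cells), size=613, replace=False)
        rows = [(*cells[i], int(rng.integers(1, 9)), 1, 1) for i in keep]
        out = bc.zero_fill(count_rows(rows), species)
        assert len(out) == 1000
        assert (out["count"] == 0).sum() == 387

    def test_duplicate_rows_rejected(self):
        rows = [("S1", "R1", 2000, "o1", "spA", 2, 1, 1),
                ("S1", "R1", 2000, "o1", "spA", 3, 1, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            bc.zero_fill(count_rows(rows), ["spA"])

    def test_empty_species_list_rejected(self):
        with pytest.raises(ValueError, match="species_list"):
            bc.zero_fill(count_rows([("S1", "R1", 2000, "o1", "spA", 2, 1, 1)]),
                         [])


class TestMinObserverAge:
    def test_first_year_is_age_one(self):
        df = count_rows([("S1", "R1", 1980, "o1", "spA", 1, 1, 1)])
        out = bc.compute_min_observer_age(df)
        assert out["observer_age"].tolist() == [1]

    def test_full_history_outside_window(self):
        window = count_rows([("S1", "R1", 1970, "o1", "spA", 1, 1, 1)])
        history = count_rows([("S1", "R9", 1966, "o1", "spA", 1, 1, 1),
                              ("S1", "R1", 1970, "o1", "spA", 1, 1, 1)])
        out = bc.compute_min_observer_age(window, full_history=history)
        assert out["observer_age"].tolist() == [5]

    def test_minimum_over_staggered_routes(self):
        df = count_rows([("S1", "R1", 1985, "o1", "spA", 1, 1, 1),
                         ("S1", "R2", 1980, "o1", "spA", 1, 1, 1),
                         ("S1", "R2", 1990, "o1", "spA", 1, 1, 1)])
        out = bc.compute_min_observer_age(df)
        by_year = out.set_index("year")["observer_age"]
        assert by_year[1985] == 6 and by_year[1990] == 11

    def test_record_before_history_rejected(self):
        window = count_rows([("S1", "R1", 1960, "o1", "spA", 1, 1, 1)])
        history = count_rows([("S1", "R1", 1966, "o1", "spA", 1, 1, 1)])
        with pytest.raises(ValueError, match="predate"):
            bc.compute_min_observer_age(window, full_history=history)


class TestApplyFilters:
    def test_hand_enumerated_fixture(self, bbs_filter_fixture):
        aged = bc.compute_min_observer_age(bbs_filter_fixture)
        filtered, report = bc.apply_filters(aged)
        assert report.n_input == 84
        assert report.removed_flags == 0
        assert report.removed_first_year == 7
        assert report.removed_short_series == 19
        assert report.removed_few_observers == 22
        assert report.removed_confounded == 0
        assert report.n_retained == 36
        assert len(filtered) == 36
        assert set(filtered["observer"]) == {"A", "D", "G"}

    def test_twelve_year_series_keeps_eleven(self):
        rows = [("S1", "R1", y, "o1", "spA", 1, 1, 1) for y in range(1980, 1992)]
        # two filler observers so the stratum passes the 3-observer rule,
        # staggered to keep |r| <= 0.7
        rows += [("S1", "R2", y, "o2", "spA", 1, 1, 1) for y in range(1975, 1990)]
        rows += [("S1", "R3", y, "o3", "spA", 1, 1, 1) for y in range(1984, 1996)]
        aged = bc.compute_min_observer_age(count_rows(rows))
        filtered, _ = bc.apply_filters(aged)
        assert (filtered[filtered["observer"] == "o1"]["year"].tolist()
                == list(range(1981, 1992)))

    def test_nine_year_series_fully_dropped(self):
        rows = [("S1", "R1", y, "o1", "spA", 1, 1, 1) for y in range(1980, 1989)]
        aged = bc.compute_min_observer_age(count_rows(rows))
        filtered, report = bc.apply_filters(aged)
        assert len(filtered) == 0
        assert report.removed_first_year + report.removed_short_series == 9

    def test_perfect_age_year_correlation_drops_stratum(self):
        # every observer first served in 1960 -> age = year - 1959 exactly
        rows = []
        for i, route in enumerate(["R1", "R2", "R3"]):
            rows += [("S1", route, y, f"o{i}", "spA", 1, 1, 1)
                     for y in range(1960, 1975)]
        aged = bc.compute_min_observer_age(count_rows(rows))
        filtered, report = bc.apply_filters(aged)
        assert len(filtered) == 0
        assert report.removed_confounded > 0
        assert report.dropped_strata == {"spA": ["S1"]}

    def test_flag_filter(self, bbs_filter_fixture):
        df = bbs_filter_fixture.copy()
        df.loc[df.index[:5], "acceptable_weather"] = 0
        aged = bc.compute_min_observer_age(df)
        _, report = bc.apply_filters(aged)
        assert report.removed_flags == 5

    def test_accounting_balances(self, bbs_filter_fixture):
        aged = bc.compute_min_observer_age(bbs_filter_fixture)
        _, report = bc.apply_filters(aged)
        assert report.n_removed + report.n_retained == report.n_input

    def test_requires_observer_age(self, bbs_filter_fixture):
        with pytest.raises(ValueError, match="observer_age"):
            bc.apply_filters(bbs_filter_fixture)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bc.FilterRules(min_series_years=0)

    def test_zero_fill_before_filtering_is_order_sensitive(self,
                                                           bbs_filter_fixture):
        # documented property: zeros added before filtering survive with
        # their series; filtering first then zero-filling resurrects unit
        # rows for dropped series
        species = ["X", "Y"]
        filled_first = bc.zero_fill(bbs_filter_fixture, species)
        aged = bc.compute_min_observer_age(filled_first)
        a, _ = bc.apply_filters(aged)
        aged2 = bc.compute_min_observer_age(bbs_filter_fixture)
        b_pre, _ = bc.apply_filters(aged2)
        b = bc.zero_fill(b_pre.drop(columns=["observer_age"]), species)
        assert len(a) != len(b) or not a.reset_index(drop=True).equals(
            b.reset_index(drop=True))
        assert len(a) == 72  # 36 retained unit-years x 2 species


def simulate_filtered(age_decline=None, seed=0, overdispersion=1.0,
                      observer_sd=0.0, trend_fn=None, routes=6,
                      tenure_mean=14):
    cfg = sd.BbsSimConfig(
        n_strata=2, routes_per_stratum=routes, year_range=(1966, 2007),
        tenure_mean=tenure_mean, baseline_log_mean=1.5,
        age_decline_fn=age_decline or (lambda a: 0.0),
        stratum_trend_fn=trend_fn or (lambda s, y: 0.0),
        observer_sd=observer_sd, overdispersion=overdispersion, seed=seed)
    cnt, _ = sd.simulate_bbs(cfg)
    aged = bc.compute_min_observer_age(cnt)
    return bc.apply_filters(aged)[0]


class TestSpeciesGamm:
    def test_recovery_of_simulated_decline(self):
        filt = simulate_filtered(
            age_decline=lambda a: math.log(0.5) * (a - 1) / 38.0, seed=5)
        fit = bc.fit_species_age_gamm(filt)
        lo, hi = fit.age_term.xmin, fit.age_term.xmax
        got = fit.proportional_age_curve(np.array([lo, hi]))[-1]
        truth = math.exp(math.log(0.5) * (hi - lo) / 38.0)
        assert got == pytest.approx(truth, abs=0.15)
        assert fit.age_smooth_p < 0.05

    def test_intercept_only_truth_fits_sample_mean(self):
        filt = simulate_filtered(seed=33)
        fit = bc.fit_species_age_gamm(filt)
        assert np.mean(fit.mu) == pytest.approx(filt["count"].mean(), rel=0.02)
        assert np.std(fit.mu) < 0.5 * np.std(filt["count"])

    def test_overdispersion_scale_estimated(self):
        filt = simulate_filtered(seed=8, overdispersion=3.0)
        fit = bc.fit_species_age_gamm(filt)
        assert fit.scale == pytest.approx(3.0, rel=0.35)

    def test_multiple_species_rejected(self):
        filt = simulate_filtered(seed=1)
        mixed = pd.concat([filt, filt.assign(species="Y")])
        with pytest.raises(ValueError, match="one species"):
            bc.fit_species_age_gamm(mixed)

    def test_too_few_records_rejected(self):
        filt = simulate_filtered(seed=1).head(10)
        with pytest.raises(GammError, match="30"):
            bc.fit_species_age_gamm(filt)

    def test_single_year_stratum_informative_error(self):
        filt = simulate_filtered(seed=1)
        one_year = filt[filt["stratum"] == "S01"]
        crippled = pd.concat([
            filt[filt["stratum"] == "S00"],
            one_year[one_year["year"] == one_year["year"].iloc[0]],
        ])
        with pytest.raises(GammError, match="single survey year"):
            bc.fit_species_age_gamm(crippled)

    def test_infinite_smoothing_matches_unpenalized_glm(self):
        # the linear-collapse oracle: all lambdas at infinity reduce the
        # model to a Poisson GLM with linear age and per-stratum linear year
        filt = simulate_filtered(
            age_decline=lambda a: math.log(0.7) * (a - 1) / 38.0, seed=9)
        cfg = GammConfig(lambda_age=np.inf, lambda_year=np.inf,
                         lambda_obs=np.inf)
        fit = PoissonGamm(filt, cfg)
        glm = sm.GLM(fit.y, fit.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)


@pytest.fixture(scope="module")
def two_fits():
    decline = lambda a: math.log(0.6) * (a - 1) / 38.0
    f1 = bc.fit_species_age_gamm(simulate_filtered(age_decline=decline,
                                                   seed=10))
    f2 = bc.fit_species_age_gamm(simulate_filtered(age_decline=decline,
                                                   seed=11))
    return {"spA": f1, "spB": f2}


class TestGroupCurves:
    def test_single_species_group_matches_own_curve(self, two_fits):
        fits = {"spA": two_fits["spA"]}
        curves = bc.group_proportional_curve(fits, {"spA": "High Monotone"})
        curve = curves["High Monotone"]
        own = two_fits["spA"].proportional_age_curve(curve.ages)
        own = own / own[0]
        np.testing.assert_allclose(curve.estimate, own, rtol=0.01, atol=0.01)

    def test_anchored_at_one(self, two_fits):
        curves = bc.group_proportional_curve(
            two_fits, {sp: "High Monotone" for sp in two_fits})
        assert curves["High Monotone"].estimate[0] == 1.0

    def test_band_contains_estimate(self, two_fits):
        curves = bc.group_proportional_curve(
            two_fits, {sp: "High Monotone" for sp in two_fits})
        c = curves["High Monotone"]
        assert np.all(c.lo <= c.estimate) and np.all(c.hi >= c.estimate)
        assert np.all(np.isfinite(c.lo)) and np.all(np.isfinite(c.hi))

    def test_shared_decline_recovered(self, two_fits):
        curves = bc.group_proportional_curve(
            two_fits, {sp: "High Monotone" for sp in two_fits})
        c = curves["High Monotone"]
        truth = math.exp(math.log(0.6) * (c.ages[-1] - c.ages[0]) / 38.0)
        assert c.estimate[-1] == pytest.approx(truth, abs=0.15)

    def test_unassigned_species_skipped(self, two_fits, caplog):
        with caplog.at_level("WARNING"):
            curves = bc.group_proportional_curve(two_fits,
                                                 {"spA": "High Monotone"})
        assert list(curves) == ["High Monotone"]
        assert curves["High Monotone"].n_species == 1


class TestPipeline:
    def test_end_to_end_two_species(self):
        cfg = sd.BbsSimConfig(n_strata=2, routes_per_stratum=6,
                              year_range=(1970, 2007), tenure_mean=14,
                              baseline_log_mean=1.5, seed=3)
        cnt, _ = sd.simulate_bbs(cfg)
        cnt2 = cnt.assign(species="spB")
        both = pd.concat([cnt, cnt2.sample(frac=0.6, random_state=0)],
                         ignore_index=True)
        fits, report, filtered = bc.run_species_pipeline(
            both, ["SYNTH1", "spB"])
        assert report.n_retained == len(filtered)
        assert set(fits) <= {"SYNTH1", "spB"}
        assert len(fits) >= 1
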