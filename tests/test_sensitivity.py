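import numpy as np
import pandas as pd
import pytest

import phenophylo as pp
from phenophylo import sensitivity as sens
from phenophylo import synthetic_data as sd


@pytest.fixture(scope="module")
def climate():
    cfg = sd.SyntheticConfig(seed=400)
    clim, _ = sd.simulate_climate((1965, 2018), cfg, seed=400)
    return clim


@pytest.fixture(scope="module")
def constant_climate():
    dates = pd.date_range("2000-01-01", "2010-12-31", freq="D")
    return sens.DailyClimate(
        pd.DataFrame({"tmean_c": 10.0, "prcp_mm": 1.0}, index=dates)
    )


class TestDailyClimate:
    def test_gap_detected(self):
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        df = pd.DataFrame({"tmean_c": 1.0, "prcp_mm": 0.0}, index=dates)
        with pytest.raises(ValueError, match="missing days"):
            sens.DailyClimate(df.drop(df.index[100]))

    def test_duplicate_dates_detected(self):
        dates = pd.date_range("2000-01-01", "2000-03-01", freq="D")
        df = pd.DataFrame({"tmean_c": 1.0, "prcp_mm": 0.0}, index=dates)
        with pytest.raises(ValueError, match="duplicate"):
            sens.DailyClimate(pd.concat([df, df.iloc[:1]]))


class TestWindowMean:
    def test_constant_series(self, constant_climate):
        assert sens.window_mean(constant_climate, 2005, 100, 30,
                                "temperature") == pytest.approx(10.0)

    def test_single_day_window_is_previous_day(self, climate):
        v = sens.window_mean(climate, 2000, 100, 1, "temperature")
        day99 = pd.Timestamp(2000, 1, 1) + pd.Timedelta(days=98)
        assert v == pytest.approx(float(climate.data.loc[day99, "tmean_c"]))

    def test_cross_year_window_matches_calendar_walk(self, climate):
        v = sens.window_mean(climate, 2001, 20, 40, "temperature")
        anchor = pd.Timestamp(2001, 1, 20)
        days = [anchor - pd.Timedelta(days=k) for k in range(1, 41)]
        manual = np.mean([float(climate.data.loc[d, "tmean_c"]) for d in days])
        assert v == pytest.approx(manual, abs=1e-12)

    def test_uncovered_window_errors(self, climate):
        with pytest.raises(ValueError, match="not covered"):
            sens.window_mean(climate, 1965, 50, 120, "temperature")

    def test_window_means_matrix_agrees_with_scalar(self, climate):
        W = sens.window_means(climate, [1990, 1995], 100, 50, "temperature")
        for i, year in enumerate((1990, 1995)):
            for L in (1, 17, 50):
                assert W[i, L - 1] == pytest.approx(
                    sens.window_mean(climate, year, 100, L, "temperature"),
                    abs=1e-10,
                )


class TestFindPreseason:
    def test_exact_linear_construction(self, climate):
        # DOY centered so the multi-year mean (hence the anchor) is exactly
        # 120; values stay real-valued to exercise the pure scan.
        years = list(range(1970, 2010))
        tbar = np.array([
            sens.window_mean(climate, y, 120, 30, "temperature") for y in years
        ])
        doy = 120.0 - 3.0 * (tbar - tbar.mean())
        pheno = sens.PhenoSeries("s", "FLD", dict(zip(years, doy)))
        res = sens.find_preseason(pheno, climate, "temperature")
        assert res.length == 30
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-9)

    def test_recovery_with_noise(self, climate):
        hits = 0
        for seed in range(40):
            ph = sd.simulate_phenology(
                climate, "s", "FLD", 100.0, 45, -3.0, 2.0, seed=seed
            )
            res = sens.find_preseason(ph, climate, "temperature")
            hits += abs(res.length - 45) <= 10
        assert hits / 40 >= 0.8

    def test_determinism(self, climate):
        ph = sd.simulate_phenology(climate, "s", "FLD", 100.0, 30, -3.0, 2.0, seed=3)
        r1 = sens.find_preseason(ph, climate, "temperature")
        r2 = sens.find_preseason(ph, climate, "temperature")
        assert r1 == r2

    def test_temperature_shift_changes_nothing_but_intercept(self, climate):
        ph = sd.simulate_phenology(climate, "s", "FLD", 100.0, 30, -3.0, 1.0, seed=4)
        shifted = sens.DailyClimate(
            climate.data.assign(tmean_c=climate.data["tmean_c"] + 5.0)
        )
        r1 = sens.find_preseason(ph, climate, "temperature")
        r2 = sens.find_preseason(ph, shifted, "temperature")
        assert (r1.length, r1.pearson_r) == (r2.length, pytest.approx(r2.pearson_r))
        s1 = sens.sensitivity_slope(ph, climate, r1)
        s2 = sens.sensitivity_slope(ph, shifted, r2)
        assert s1.slope == pytest.approx(s2.slope, abs=1e-9)
        assert s2.intercept == pytest.approx(s1.intercept - 5.0 * s1.slope, abs=1e-6)


class TestSensitivitySlope:
    def test_noiseless_slope_recovered(self, climate):
        ph = sd.simulate_phenology(climate, "s", "FLD", 100.0, 30, -3.0, 0.0, seed=0)
        pre = sens.find_preseason(ph, climate, "temperature")
        res = sens.sensitivity_slope(ph, climate, pre)
        assert pre.length == 30
        assert res.slope == pytest.approx(-3.0, abs=0.1)  # DOY integer rounding

    def test_regression_identity(self, climate):
        ph = sd.simulate_phenology(climate, "s", "FLD", 100.0, 30, -3.0, 2.0, seed=5)
        pre = sens.find_preseason(ph, climate, "temperature")
        res = sens.sensitivity_slope(ph, climate, pre)
        years = ph.years
        doy = np.array([ph.doy_by_year[y] for y in years], dtype=float)
        pred = np.array([
            sens.window_mean(climate, y, pre.anchor_doy, pre.length, "temperature")
            for y in years
        ])
        assert res.slope == pytest.approx(
            res.pearson_r * doy.std() / pred.std(), abs=1e-10
        )

    def test_mean_slope_unbiased(self, climate):
        slopes = []
        for seed in range(60):
            ph = sd.simulate_phenology(
                climate, "s", "FLD", 100.0, 45, -3.0, 2.0, seed=seed
            )
            pre = sens.find_preseason(ph, climate, "temperature")
            slopes.append(sens.sensitivity_slope(ph, climate, pre).slope)
        assert abs(np.mean(slopes) + 3.0) < 0.3


class TestFilterMinYears:
    @staticmethod
    def _series(species, n_fld, n_ffd):
        mk = lambda ph, n: sens.PhenoSeries(
            species, ph, {1960 + i: 100 for i in range(n)}
        )
        d = {}
        if n_fld:
            d["FLD"] = mk("FLD", n_fld)
        if n_ffd:
            d["FFD"] = mk("FFD", n_ffd)
        return d

    def test_threshold_boundary(self):
        table = {
            "short": self._series("short", 49, 60),
            "exact": self._series("exact", 50, 50),
            "missing_ffd": self._series("missing_ffd", 60, 0),
        }
        kept = sens.filter_min_years(table, 50)
        assert sorted(kept) == ["exact"]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        table, expect = {}, []
        for i in range(30):
            nf, ng = int(rng.integers(40, 60)), int(rng.integers(40, 60))
            sp = f"sp{i:02d}"
            table[sp] = self._series(sp, nf, ng)
            if nf >= 50 and ng >= 50:
                expect.append(sp)
        assert sorted(sens.filter_min_years(table, 50)) == expect
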