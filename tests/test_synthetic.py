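import numpy as np
import pytest

import phenophylo as pp
from phenophylo import synthetic_data as sd


class TestYuleTree:
    def test_small_tree_valid_and_ultrametric(self):
        t = pp.simulate_yule_tree(3, seed=1)
        assert t.n_tips == 3
        assert pp.check_ultrametric(t, rel_tol=1e-9)[0]

    def test_determinism(self):
        t1 = pp.simulate_yule_tree(10, birth_rate=2.0, seed=42)
        t2 = pp.simulate_yule_tree(10, birth_rate=2.0, seed=42)
        assert t1.write_newick() == t2.write_newick()

    def test_mean_height_matches_pure_birth_expectation(self):
        n, rate = 16, 1.0
        expected = sum(1.0 / k for k in range(2, n + 1)) / rate
        heights = [
            pp.check_ultrametric(pp.simulate_yule_tree(n, rate, seed=s))[1]
            for s in range(400)
        ]
        se = np.std(heights) / np.sqrt(len(heights))
        assert abs(np.mean(heights) - expected) < 4 * se + 0.02


class TestSimulateTrait:
    def test_zero_variance_is_constant(self, yule64):
        x = pp.simulate_trait(yule64, "BM", mu=3.0, sigma2=0.0, seed=0)
        assert set(x.values()) == {3.0}

    def test_bm_empirical_covariance(self):
        tree = pp.simulate_yule_tree(8, seed=90)
        cov = pp.phylo_covariance(tree)
        rng = np.random.default_rng(91)
        draws = np.array([
            [v for _, v in sorted(pp.simulate_trait(
                tree, "BM", sigma2=2.0, seed=int(rng.integers(2**31))).items())]
            for _ in range(4000)
        ])
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, 2.0 * cov.matrix,
                                   atol=0.05 * 2.0 * cov.matrix.max() + 0.05)

    def test_ou_converges_to_bm_at_tiny_alpha(self):
        tree = pp.simulate_yule_tree(10, seed=92)
        from phenophylo.synthetic_data import trait_covariance

        _, Sbm = trait_covariance(tree, "BM", 1.0)
        _, Sou = trait_covariance(tree, "OU", 1.0, alpha=1e-8)
        np.testing.assert_allclose(Sou, Sbm, rtol=1e-6)

    def test_wn_is_diagonal(self, yule64):
        from phenophylo.synthetic_data import trait_covariance

        _, S = trait_covariance(yule64, "WN", 3.0)
        np.testing.assert_array_equal(S, 3.0 * np.eye(64))


class TestSimulateClimate:
    def test_flat_configuration_is_constant(self):
        cfg = sd.SyntheticConfig(
            seasonal_amplitude_c=0.0, daily_noise_sd_c=0.0, year_effect_sd_c=0.0
        )
        clim, _ = sd.simulate_climate((2000, 2002), cfg, seed=0)
        assert clim.data["tmean_c"].std() == pytest.approx(0.0, abs=1e-12)
        assert clim.data["tmean_c"].iloc[0] == pytest.approx(cfg.annual_mean_c)

    def test_determinism(self):
        cfg = sd.SyntheticConfig()
        c1, _ = sd.simulate_climate((2000, 2005), cfg, seed=7)
        c2, _ = sd.simulate_climate((2000, 2005), cfg, seed=7)
        assert c1.data.equals(c2.data)

    def test_year_effects_recoverable_by_averaging(self):
        # small daily noise so the yearly average isolates the injected effect
        cfg = sd.SyntheticConfig(daily_noise_sd_c=0.3, ar1_coef=0.3,
                                 year_effect_sd_c=1.0)
        clim, effects = sd.simulate_climate((1970, 2019), cfg, seed=8)
        df = clim.data.copy()
        df["year"] = df.index.year
        df["doy"] = df.index.dayofyear
        season = cfg.annual_mean_c + cfg.seasonal_amplitude_c * np.cos(
            2 * np.pi * (df["doy"] - cfg.peak_doy) / 365.25
        )
        resid = (df["tmean_c"] - season).groupby(df["year"]).mean()
        recovered = resid - resid.mean()
        injected = (lambda s: s - s.mean())(
            np.array([effects[y] for y in resid.index])
        )
        assert np.max(np.abs(recovered.to_numpy() - injected)) < 0.1

    def test_precipitation_nonnegative(self):
        clim, _ = sd.simulate_climate((2000, 2003), sd.SyntheticConfig(), seed=9)
        assert (clim.data["prcp_mm"] >= 0).all()


class TestSimulatePhenology:
    def test_determinism_and_integer_doy(self):
        clim, _ = sd.simulate_climate((1990, 2010), sd.SyntheticConfig(), seed=10)
        p1 = sd.simulate_phenology(clim, "s", "FLD", 100.0, 30, -3.0, 2.0, seed=11)
        p2 = sd.simulate_phenology(clim, "s", "FLD", 100.0, 30, -3.0, 2.0, seed=11)
        assert p1.doy_by_year == p2.doy_by_year
        assert all(isinstance(v, (int, np.integer)) for v in p1.doy_by_year.values())

    def test_null_slope_estimates_center_on_zero(self):
        from phenophylo import sensitivity as sens

        clim, _ = sd.simulate_climate((1960, 2018), sd.SyntheticConfig(), seed=12)
        slopes = []
        for seed in range(40):
            ph = sd.simulate_phenology(clim, "s", "FLD", 100.0, 30, 0.0, 2.0,
                                       seed=seed)
            pre = sens.find_preseason(ph, clim, "temperature")
            slopes.append(sens.sensitivity_slope(ph, clim, pre).slope)
        assert abs(np.mean(slopes)) < 0.5


class TestSimulateStation:
    def test_fixture_files_deterministic(self, tmp_path):
        cfg = sd.SyntheticConfig(seed=5, n_species=8, years=(2000, 2012))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.simulate_station(cfg).write(d1)
        sd.simulate_station(cfg).write(d2)
        for name in ("tree.nwk", "climate.csv", "phenology.csv",
                     "functional_traits.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_null_station_shows_no_signal(self):
        cfg = sd.SyntheticConfig(
            seed=6, n_species=24, years=(2000, 2015), trait_model="WN",
            noise_frac=1.0,
        )
        fx = sd.simulate_station(cfg)
        base = fx.truth["base_doy"]["FLD"]
        res = pp.permutation_pvalue(fx.tree, base, 199, seed=1)
        assert res.K < 1.0 or res.p_value > 0.05

    def test_bm_station_shows_signal(self):
        cfg = sd.SyntheticConfig(seed=7, n_species=32, years=(2000, 2015),
                                 tree_effect_days=0.0, noise_frac=0.05)
        fx = sd.simulate_station(cfg)
        base = fx.truth["base_doy"]["FLD"]
        comp = pp.fit_all(fx.tree, base)
        assert comp.selected in {"BM", "OU"}
        res = pp.permutation_pvalue(fx.tree, base, 199, seed=2)
        assert res.p_value < 0.05

    def test_readers_roundtrip_fixture(self, tmp_path):
        from phenophylo import pgls, sensitivity as sens, treeio

        cfg = sd.SyntheticConfig(seed=8, n_species=6, years=(2005, 2012))
        fx = sd.simulate_station(cfg)
        paths = fx.write(tmp_path)
        tree = treeio.parse_newick(paths["tree"].read_text())
        assert tree.taxa == fx.tree.taxa
        clim = sens.read_climate_csv(paths["climate"])
        assert len(clim.data) == len(fx.climate.data)
        series = sens.read_phenology_csv(paths["phenology"])
        assert set(series) == set(fx.phenology)
        sp = sorted(series)[0]
        assert series[sp]["FLD"].doy_by_year == fx.phenology[sp]["FLD"].doy_by_year
        ft = pgls.read_functional_traits_csv(paths["functional_traits"])
        assert list(ft.data.columns) == ["life_form", "pollination", "leaf_habit"]
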