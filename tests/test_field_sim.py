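"""Field simulation: weather IO, solar geometry, Wilcoxon, the contrast."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from hygrotherm.field_sim import (
    SimConfig, WeatherConfig, percent_difference, read_weather,
    simulate_resting_costs, solar_elevation, wilcoxon_signed_rank,
)
from hygrotherm.scholander import ScholanderModel


class TestReadWeather:
    def _write(self, tmp_path, rows, header="timestamp,t_air_c,rh_pct,solar_wm2,wind_ms"):
        p = tmp_path / "w.csv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_wellformed_rows(self, tmp_path):
        p = self._write(tmp_path, ["2023-05-01 00:00,12.5,80,0,2.0",
                                   "2023-05-01 01:00,12.0,82,0,1.5"])
        df = read_weather(p)
        assert len(df) == 2
        assert df.loc[0, "t_air"] == 12.5

    def test_fahrenheit_conversion(self, tmp_path):
        p = self._write(tmp_path, ["2023-05-01 00:00,68.0,50,0,2.0"])
        df = read_weather(p, WeatherConfig(temp_unit="F"))
        assert df.loc[0, "t_air"] == pytest.approx(20.0, abs=1e-12)

    def test_mesonet_dialect_units(self, tmp_path):
        p = self._write(tmp_path, ["2023-05-01 00:00,68.0,50,100,10.0"],
                        header="valid,tmpf,relh,srad,sped")
        df = read_weather(p, WeatherConfig(dialect="mesonet"))
        assert df.loc[0, "t_air"] == pytest.approx(20.0)
        assert df.loc[0, "wind"] == pytest.approx(4.4704)

    def test_missing_value_dropped_and_logged(self, tmp_path, caplog):
        p = self._write(tmp_path, ["2023-05-01 00:00,12.5,80,0,2.0",
                                   "2023-05-01 01:00,12.0,,0,1.5"])
        with caplog.at_level("INFO", logger="hygrotherm"):
            df = read_weather(p)
        assert len(df) == 1
        assert "dropped 1 of 2" in caplog.text

    def test_duplicate_timestamps_rejected(self, tmp_path):
        p = self._write(tmp_path, ["2023-05-01 00:00,12.5,80,0,2.0",
                                   "2023-05-01 00:00,12.0,70,0,1.5"])
        with pytest.raises(ValueError, match="duplicate"):
            read_weather(p)


class TestSolarElevation:
    def test_equator_equinox_noon_near_zenith(self):
        # scan around noon: the equation of time shifts true noon slightly
        times = pd.date_range("2023-03-20 11:00", "2023-03-20 13:00", freq="min")
        elev = solar_elevation(times.to_numpy(), 0.0, 0.0, 0.0)
        assert elev.max() > 89.0

    def test_solar_midnight_below_horizon(self):
        e = solar_elevation(np.datetime64("2023-06-21T00:00"), 42.1, -93.59, -6.0)
        assert e < 0

    def test_ames_summer_solstice_noon(self):
        # 42.1°N on Jun 21: 90 - 42.1 + 23.44 = 71.3 degrees
        times = pd.date_range("2023-06-21 11:00", "2023-06-21 14:00", freq="min")
        elev = solar_elevation(times.to_numpy(), 42.106328, -93.589807, -6.0)
        assert elev.max() == pytest.approx(71.3, abs=0.5)


class TestWilcoxon:
    def test_all_positive_n5_one_sided(self):
        w, p, info = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5],
                                          alternative="greater")
        assert info["method"] == "exact"
        assert p == pytest.approx(1.0 / 32.0, abs=1e-12)

    def test_identical_pairs_degenerate(self):
        x = np.arange(5.0)
        w, p, info = wilcoxon_signed_rank(x, x)
        assert info["degenerate"] and p == 1.0

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_exact_matches_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0.3, 1.0, n)
        d[d == 0] = 0.1
        w_obs, p, info = wilcoxon_signed_rank(d, alternative="greater")
        ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
        ge = sum(np.sum(ranks[np.array(signs, dtype=bool)]) >= w_obs
                 for signs in itertools.product([0, 1], repeat=n))
        assert p == pytest.approx(ge / 2 ** n, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.2, 1.0, 12)
        w, p, _ = wilcoxon_signed_rank(d)
        stat, p_ref = scipy_wilcoxon(d, method="exact")
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_normal_approx_close_to_exact_at_n25(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.25, 1.0, 25)
        _, p_exact, _ = wilcoxon_signed_rank(d, exact_max_n=25)
        _, p_norm, _ = wilcoxon_signed_rank(d, exact_max_n=10)
        assert p_norm == pytest.approx(p_exact, abs=0.01)


class TestPercentDifference:
    def test_printed_median_pair(self):
        assert 7.5 <= percent_difference(0.860, 0.925) <= 7.6

    def test_trivial_values(self):
        assert percent_difference(1.0, 1.0) == 0.0
        assert percent_difference(1.0, 1.1) == pytest.approx(10.0)

    def test_nonpositive_dry_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


def _flat_models(scale=1.0):
    dry = ScholanderModel(lct=27.6, slope=-0.038, plateau=0.62)
    humid = ScholanderModel(lct=27.6, slope=-0.038 * scale,
                            plateau=0.62 * scale)
    return dry, humid


class TestSimulation:
    def test_identical_models_no_noise(self, short_weather, morph, optics):
        dry, _ = _flat_models()
        res = simulate_resting_costs(short_weather, dry, dry, morph, optics,
                                     SimConfig(seed=0))
        assert res.percent_difference == 0.0
        assert res.wilcoxon_p == 1.0

    def test_constructed_seven_percent_ratio(self, short_weather, morph, optics):
        dry, humid = _flat_models(scale=1.07)
        res = simulate_resting_costs(short_weather, dry, humid, morph, optics,
                                     SimConfig(seed=0))
        assert res.percent_difference == pytest.approx(7.000, abs=1e-9)

    def test_noise_free_sim_seed_invariant(self, short_weather, morph, optics):
        dry, humid = _flat_models(scale=1.02)
        r1 = simulate_resting_costs(short_weather, dry, humid, morph, optics,
                                    SimConfig(seed=1))
        r2 = simulate_resting_costs(short_weather, dry, humid, morph, optics,
                                    SimConfig(seed=99))
        assert r1.median_dry == r2.median_dry
        assert r1.median_humid == r2.median_humid

    def test_same_seed_bit_identical(self, short_weather, morph, optics,
                                     swallow_models):
        dry, humid = swallow_models
        r1 = simulate_resting_costs(short_weather, dry, humid, morph, optics,
                                    SimConfig(seed=12))
        r2 = simulate_resting_costs(short_weather, dry, humid, morph, optics,
                                    SimConfig(seed=12))
        pd.testing.assert_frame_equal(r1.hourly, r2.hourly)

    def test_hour_ordering_invariance(self, short_weather, morph, optics):
        dry, humid = _flat_models(scale=1.03)
        shuffled = short_weather.sample(frac=1.0, random_state=4).reset_index(drop=True)
        r1 = simulate_resting_costs(short_weather, dry, humid, morph, optics,
                                    SimConfig(seed=2))
        r2 = simulate_resting_costs(shuffled, dry, humid, morph, optics,
                                    SimConfig(seed=2))
        assert r1.median_dry == pytest.approx(r2.median_dry)
        assert r1.median_humid == pytest.approx(r2.median_humid)

    def test_raising_humid_lct_weakly_raises_humid_median(
            self, short_weather, morph, optics):
        dry = ScholanderModel(lct=27.6, slope=-0.038, plateau=0.62)
        medians = []
        for lct in (26.0, 28.0, 30.0):
            humid = ScholanderModel(lct=lct, slope=-0.038, plateau=0.62)
            res = simulate_resting_costs(short_weather, dry, humid, morph,
                                         optics, SimConfig(seed=3))
            medians.append(res.median_humid)
        assert medians[0] <= medians[1] <= medians[2]

    def test_inclusion_filter_matches_direct_count(self, short_weather, morph,
                                                   optics, swallow_models):
        dry, humid = swallow_models
        cfg = SimConfig(seed=5)
        res = simulate_resting_costs(short_weather, dry, humid, morph, optics, cfg)
        ts = short_weather["timestamp"]
        in_season = (ts.dt.month * 100 + ts.dt.day).between(401, 731)
        direct = (short_weather["t_air"].between(15.0, 32.0) & in_season).sum()
        assert len(res.hourly) == direct
        assert res.fraction_included == pytest.approx(direct / in_season.sum())

    def test_empty_filter_errors(self, morph, optics, swallow_models):
        dry, humid = swallow_models
        w = pd.DataFrame({
            "timestamp": pd.date_range("2023-05-01", periods=5, freq="h"),
            "t_air": np.full(5, -20.0), "rh": np.full(5, 50.0),
            "solar": np.zeros(5), "wind": np.ones(5)})
        with pytest.raises(ValueError, match="inclusion"):
            simulate_resting_costs(w, dry, humid, morph, optics, SimConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(t_range=(32.0, 15.0))
        with pytest.raises(ValueError):
            SimConfig(latitude=95.0)
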