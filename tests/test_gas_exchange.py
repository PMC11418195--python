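"""Respirometry processing: humidity algebra, corrections, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hygrotherm.gas_exchange import (
    GasTrace, Phase, ProcessingConfig, TrialInfo, WindowMethod,
    FlaggedRecordError, InfeasibleHumidityError, NoStableWindowError,
    compute_gas_exchange, correct_response, energy_partition,
    find_stable_window, latent_heat_vaporization, process_trace,
    records_from_csv, records_to_csv, rh_for_vpd, svp, vpd,
)
from hygrotherm.synthetic import TrueTrialSpec, gen_respirometry_trace, _steady_state


class TestHumidityAlgebra:
    def test_svp_matches_printed_dry_air_example(self):
        # dry air at 10°C has a deficit of 1.22 kPa
        assert 1.22 <= svp(10.0) <= 1.23

    def test_svp_hand_value_at_25C(self):
        # Buck formula evaluated by hand: 0.61121*exp(17.502*25/265.97)
        assert svp(25.0) == pytest.approx(3.167, abs=0.005)

    def test_svp_monotone_increasing(self):
        temps = np.linspace(-40, 60, 200)
        assert np.all(np.diff(svp(temps)) > 0)
        assert svp(32.0) > svp(10.0)

    @pytest.mark.parametrize("t", [-41.0, 60.5])
    def test_svp_domain_error(self, t):
        with pytest.raises(ValueError):
            svp(t)

    def test_equivalent_humidity_across_temperatures(self):
        # the RH at 32°C matching dry air at 10°C
        rh = rh_for_vpd(32.0, vpd(10.0, 0.0))
        assert 74.15 <= rh <= 74.35

    def test_saturated_air_has_zero_deficit(self):
        for t in (0.0, 10.0, 25.0, 40.0):
            assert vpd(t, 100.0) == pytest.approx(0.0, abs=1e-12)

    @given(t=st.floats(-30, 50), rh=st.floats(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_vpd_identity_and_inverse(self, t, rh):
        d = vpd(t, rh)
        assert d + svp(t) * rh / 100.0 == pytest.approx(svp(t), rel=1e-12)
        assert rh_for_vpd(t, d) == pytest.approx(rh, abs=1e-9)

    def test_infeasible_target_vpd(self):
        with pytest.raises(InfeasibleHumidityError):
            rh_for_vpd(10.0, svp(10.0) + 0.1)


def _uniform_trace(values_co2, values_wvp, dt=1.0, t_chamber=25.0):
    n = len(values_co2)
    time = np.arange(n) * dt
    return GasTrace(time=time, co2_frac=values_co2, wvp=values_wvp,
                    flow_in=np.full(n, 4.0), phase=np.array(["sample"] * n),
                    t_chamber=np.full(n, t_chamber),
                    p_baro=np.full(n, 101.325))


class TestResponseCorrection:
    def test_constant_trace_unchanged(self):
        tr = _uniform_trace(np.full(100, 5e-4), np.full(100, 1.0))
        out = correct_response(tr, tau=0.45, lag=0.0)
        np.testing.assert_allclose(out.co2_frac, tr.co2_frac, rtol=1e-12)
        np.testing.assert_allclose(out.wvp, tr.wvp, rtol=1e-12)

    def test_zero_tau_zero_lag_is_identity(self):
        rng = np.random.default_rng(0)
        co2 = 5e-4 + 1e-5 * rng.standard_normal(50)
        tr = _uniform_trace(co2, np.full(50, 1.0))
        out = correct_response(tr, tau=0.0, lag=0.0)
        np.testing.assert_array_equal(out.co2_frac, tr.co2_frac)

    def test_step_through_first_order_chamber_is_inverted(self):
        # forward-simulate the washout ODE (the independent oracle), then
        # check the correction recovers the step: tau = V/FR = 1.8/4 min
        tau_min = 1.8 / 4.0
        tau_s = tau_min * 60.0
        t = np.arange(0.0, 600.0, 1.0)
        step_at, lo, hi = 100.0, 2e-4, 6e-4
        filtered = np.where(t < step_at, lo,
                            hi + (lo - hi) * np.exp(-(t - step_at) / tau_s))
        tr = _uniform_trace(filtered, np.full(t.size, 1.0))
        out = correct_response(tr, tau=tau_min, lag=0.0)
        true_step = np.where(t < step_at, lo, hi)
        after = t >= step_at + 2.0   # one sample past the discrete-gradient edge
        np.testing.assert_allclose(out.co2_frac[after], true_step[after], rtol=0.02)

    def test_band_limited_roundtrip_l2_error(self):
        # slowly varying signal -> filter -> correct ~ identity (<2% L2)
        tau_s = 27.0
        t = np.arange(0.0, 3000.0, 1.0)
        x = 5e-4 + 1e-4 * np.sin(2 * np.pi * t / 600.0)
        filtered = np.empty_like(x)
        filtered[0] = x[0]
        for i in range(1, t.size):   # exact exponential-hold integration
            a = np.exp(-1.0 / tau_s)
            filtered[i] = a * filtered[i - 1] + (1 - a) * x[i]
        tr = _uniform_trace(filtered, np.full(t.size, 1.0))
        out = correct_response(tr, tau=tau_s / 60.0, lag=0.0)
        sl = t > 5 * tau_s
        rel_l2 = (np.linalg.norm(out.co2_frac[sl] - x[sl])
                  / np.linalg.norm(x[sl]))
        assert rel_l2 < 0.02

    def test_resampling_invariance(self):
        tau_s = 27.0
        for dt in (1.0, 2.0):
            t = np.arange(0.0, 2000.0, dt)
            x = 5e-4 + 1e-4 * np.sin(2 * np.pi * t / 700.0)
            a = np.exp(-dt / tau_s)
            filtered = np.empty_like(x)
            filtered[0] = x[0]
            for i in range(1, t.size):
                filtered[i] = a * filtered[i - 1] + (1 - a) * x[i]
            tr = _uniform_trace(filtered, np.full(t.size, 1.0), dt=dt)
            out = correct_response(tr, tau=tau_s / 60.0, lag=0.0)
            sl = t > 5 * tau_s
            assert np.interp(1000.0, t[sl], out.co2_frac[sl]) == pytest.approx(
                5e-4 + 1e-4 * np.sin(2 * np.pi * 1000.0 / 700.0), rel=0.01)


class TestStableWindow:
    def test_constant_series(self):
        t = np.arange(200.0)
        w = find_stable_window(t, np.full(200, 3.3), duration=60)
        assert w.mean_value == pytest.approx(3.3)

    def test_low_plateau_selected(self):
        t = np.arange(400.0)
        v = np.where(t < 200, 8.0, 2.0)
        w = find_stable_window(t, v, duration=60)
        assert w.mean_value == pytest.approx(2.0)
        assert w.start >= 200

    def test_matches_exhaustive_search(self, rng):
        t = np.arange(600.0)
        v = 1.0 + 0.005 * rng.standard_normal(600)
        v[250:340] -= 0.05    # planted low stable stretch
        got = find_stable_window(t, v, duration=60, sd_threshold=0.01)
        # brute force: every 60-sample window, same criterion
        best = None
        for i in range(600 - 60 + 1):
            w = v[i:i + 60]
            sd = np.std(w, ddof=1)
            if sd > 0.01 or np.max(np.abs(w - w.mean())) > 4 * sd:
                continue
            if best is None or w.mean() < best[1]:
                best = (i, w.mean())
        assert got.mean_value == pytest.approx(best[1], rel=1e-12)
        assert got.start == best[0]

    def test_no_stable_window_raises(self, rng):
        t = np.arange(200.0)
        v = rng.standard_normal(200)
        with pytest.raises(NoStableWindowError):
            find_stable_window(t, v, duration=60, sd_threshold=1e-6)

    def test_asymptote_mode_recovers_limit(self):
        t = np.arange(0.0, 400.0)
        v = 2.5 - 1.2 * np.exp(-t / 80.0)
        w = find_stable_window(t, v, duration=60, mode=WindowMethod.ASYMPTOTE)
        assert w.mean_value == pytest.approx(2.5, abs=1e-6)


class TestMassBalance:
    def test_no_difference_means_no_exchange(self):
        vco2, ewl, flags = compute_gas_exchange(4.2e-4, 4.2e-4, 1.0, 1.0,
                                                flow_lpm=4.0, p_baro_kpa=101.325)
        assert vco2 == pytest.approx(0.0, abs=1e-12)
        assert ewl == pytest.approx(0.0, abs=1e-12)

    def test_dry_air_hand_mass_balance(self):
        # delta F = 2.25e-4 at 4 L/min, dry: ~ 4000 * 2.25e-4 = 0.9 ml/min
        vco2, _, _ = compute_gas_exchange(4.2e-4 + 2.25e-4, 4.2e-4, 0.0, 0.0,
                                          flow_lpm=4.0, p_baro_kpa=101.325)
        assert vco2 == pytest.approx(0.9, rel=2e-3)

    @pytest.mark.parametrize("flow", [1.0, 4.0, 6.0])
    @pytest.mark.parametrize("rh_in", [0.0, 60.0])
    @pytest.mark.parametrize("truth", [(0.3, 1.0), (0.9, 5.0), (2.0, 20.0)])
    def test_closure_against_steady_state_simulator(self, flow, rh_in, truth):
        true_vco2, true_ewl = truth
        spec = TrueTrialSpec(treatment="humid" if rh_in else "dry", t_set=30.0,
                             true_vco2=true_vco2, true_ewl=true_ewl, flow_lpm=flow)
        try:
            f_ce, wvp_ss, _ = _steady_state(spec)
        except InfeasibleHumidityError:
            pytest.skip("steady state would exceed saturation at this flow")
        vco2, ewl, _ = compute_gas_exchange(
            f_ce, 4.2e-4, wvp_ss, spec.incurrent_wvp,
            flow_lpm=flow, p_baro_kpa=spec.p_baro_kpa, rq=spec.rq)
        assert vco2 == pytest.approx(true_vco2, rel=0.01)
        assert ewl == pytest.approx(true_ewl, rel=0.01)

    def test_small_negative_clamped_large_rejected(self):
        _, _, flags = compute_gas_exchange(4.2e-4 * 0.99, 4.2e-4, 1.0, 1.0,
                                           flow_lpm=4.0, p_baro_kpa=101.325)
        assert "co2_clamped" in flags
        with pytest.raises(FlaggedRecordError):
            compute_gas_exchange(4.2e-4 * 0.9, 4.2e-4, 1.0, 1.0,
                                 flow_lpm=4.0, p_baro_kpa=101.325)


class TestEnergyPartition:
    def test_hand_values(self):
        # V.O2 = 1 ml/min at RER 0.71 -> q = 19.666 J/ml -> 0.3278 W
        mhp, ehl, ratio = energy_partition(0.71, 1.0, rer=0.71, t_evap=40.0)
        assert mhp == pytest.approx(0.3278, abs=5e-4)
        # 1 mg/min at lambda(40°C) = 2.406 J/mg -> 0.0401 W
        assert ehl == pytest.approx(0.0401, abs=2e-4)
        assert ratio == pytest.approx(ehl / mhp)

    def test_zero_water_loss(self):
        _, ehl, ratio = energy_partition(1.0, 0.0)
        assert ehl == 0.0 and ratio == 0.0

    def test_zero_vco2_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            energy_partition(0.0, 1.0)

    @given(scale=st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_each_argument(self, scale):
        mhp1, ehl1, _ = energy_partition(1.0, 1.0)
        mhp_s, _, _ = energy_partition(scale, 1.0)
        _, ehl_s, _ = energy_partition(1.0, scale)
        assert mhp_s == pytest.approx(scale * mhp1, rel=1e-12)
        assert ehl_s == pytest.approx(scale * ehl1, rel=1e-12)

    def test_latent_heat_declines_with_temperature(self):
        assert latent_heat_vaporization(40.0) == pytest.approx(2.406, abs=1e-3)
        assert latent_heat_vaporization(0.0) > latent_heat_vaporization(40.0)


class TestFullPipeline:
    @pytest.mark.parametrize("treatment", ["dry", "humid"])
    @pytest.mark.parametrize("noisy", [False, True])
    def test_end_to_end_recovers_truth(self, treatment, noisy):
        spec = TrueTrialSpec(treatment=treatment, true_vco2=0.9, true_ewl=5.0,
                             co2_noise_sd=2e-6 if noisy else 0.0,
                             wvp_noise_sd=2e-3 if noisy else 0.0)
        trace, truth = gen_respirometry_trace(spec, seed=3)
        rec = process_trace(trace, TrialInfo("b01", treatment, spec.t_set),
                            ProcessingConfig(lag_s=spec.lag_s,
                                             tau_min=truth["tau_min"]))
        assert rec.vco2 == pytest.approx(0.9, rel=0.01)
        assert rec.ewl == pytest.approx(5.0, rel=0.01)
        assert rec.ehl_mhp > 0
        assert rec.ewl_vpd == pytest.approx(rec.ewl / rec.vpd)

    def test_records_csv_roundtrip(self, tmp_path):
        spec = TrueTrialSpec()
        trace, truth = gen_respirometry_trace(spec, seed=1)
        rec = process_trace(trace, TrialInfo("b01", "dry", spec.t_set),
                            ProcessingConfig(lag_s=spec.lag_s,
                                             tau_min=truth["tau_min"]))
        path = tmp_path / "records.csv"
        records_to_csv([rec], path)
        df = records_from_csv(path)
        assert len(df) == 1
        assert df.loc[0, "vco2"] == pytest.approx(rec.vco2)

    def test_trace_csv_roundtrip_and_validation(self, tmp_path):
        spec = TrueTrialSpec()
        trace, _ = gen_respirometry_trace(spec, seed=1)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = GasTrace.from_csv(path)
        np.testing.assert_allclose(back.co2_frac, trace.co2_frac)
        assert set(back.phase) == {Phase.BASELINE.value, Phase.SAMPLE.value}
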