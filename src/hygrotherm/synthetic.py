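"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed, emits exactly the
schema its reader expects, and returns (or writes) a truth record so each
pipeline stage has a closed-loop test: generate → process → compare to
truth.

* Respirometry traces: a single well-mixed chamber (first-order washout,
  time constant V/FR — 1.8 L at 4 L min⁻¹ gives 0.45 min) with analyzer
  lag and Gaussian sensor noise, alternating baseline/sample phases.
* Bird populations: observations drawn from a known segmented
  thermal-response model with per-bird random slope deviations.
* Weather: phenomenological diurnal + seasonal sinusoid with AR(1)
  anomalies, humidity negatively coupled to the temperature anomaly,
  clear-sky solar shaped by solar elevation under stochastic cloudiness,
  log-normal wind.  Defaults emulate a central-Iowa (Ames-like) breeding
  season, calibrated so roughly 65% of Apr–Jul hours fall in 15–32°C.
* Reflectance: smooth bounded spectra on the 350–2002 nm, 1-nm grid,
  plus a synthetic smooth solar irradiance spectrum for weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gas_exchange import (MG_WATER_PER_L_VAPOR, GasTrace, Phase,
                           InfeasibleHumidityError, svp)
from .scholander import ScholanderModel
from .field_sim import solar_elevation

__all__ = [
    "TrueTrialSpec", "WeatherGenSpec", "gen_respirometry_trace",
    "gen_bird_population", "gen_weather", "gen_reflectance",
    "gen_solar_irradiance", "tree_swallow_models",
]

AMBIENT_CO2_FRAC = 4.2e-4      # ~420 ppm incurrent CO2
DRY_INCURRENT_WVP_KPA = 0.004  # residual vapor after desiccant columns


def tree_swallow_models() -> tuple[ScholanderModel, ScholanderModel]:
    """Default (dry, humid) thermal-response models for a ~19 g swallow.

    Slopes (−0.038 / −0.040 ml CO2 min⁻¹ °C⁻¹) and lower critical
    temperatures (27.6 / 29.2 °C) follow published breakpoint fits for
    tree swallows under dry and 60%-RH air; residual SDs (0.057 / 0.060
    ml min⁻¹) match the reported spread.  Absolute thermoneutral levels
    are study-specific and never reported with the fits, so the plateau
    is set to a typical resting value (0.62 ml CO2 min⁻¹, i.e. ~0.87 ml
    O2 min⁻¹ at RER 0.71) with the humid plateau 2% above dry, matching
    the observed within-TNZ elevation.
    """
    dry = ScholanderModel(lct=27.6, slope=-0.038, plateau=0.62,
                          sigma_below=0.057, sigma_above=0.057,
                          sigma_slope=0.008)
    humid = ScholanderModel(lct=29.2, slope=-0.040, plateau=0.62 * 1.02,
                            sigma_below=0.060, sigma_above=0.060,
                            sigma_slope=0.008)
    return dry, humid


# -- respirometry traces -------------------------------------------------

@dataclass
class TrueTrialSpec:
    """Ground truth and plumbing for one simulated respirometry trial."""

    bird_id: str = "b01"
    treatment: str = "dry"            # "dry" or "humid"
    t_set: float = 23.0               # °C, from the design grid {15,19,23,30,32}
    true_vco2: float = 0.9            # ml CO2 min⁻¹ STP
    true_ewl: float = 5.0             # mg H2O min⁻¹
    true_t_b: float = 41.0            # °C
    chamber_volume_l: float = 1.8
    flow_lpm: float = 4.0             # incurrent, STP
    lag_s: float = 5.0
    rq: float = 0.71
    p_baro_kpa: float = 98.0          # ~290 m elevation
    co2_noise_sd: float = 2e-6        # fraction units
    wvp_noise_sd: float = 0.002       # kPa
    baseline_s: float = 300.0
    sample_s: float = 600.0
    n_cycles: int = 3
    dt_s: float = 1.0

    def __post_init__(self) -> None:
        if self.treatment not in ("dry", "humid"):
            raise ValueError("treatment must be 'dry' or 'humid'")
        for name in ("true_vco2", "true_ewl", "chamber_volume_l", "flow_lpm"):
            if getattr(self, name) < 0 or (name in ("chamber_volume_l", "flow_lpm")
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @property
    def incurrent_wvp(self) -> float:
        if self.treatment == "dry":
            return DRY_INCURRENT_WVP_KPA
        return 0.60 * svp(self.t_set)


def _steady_state(spec: TrueTrialSpec) -> tuple[float, float, float]:
    """Excurrent steady state (co2 fraction, wvp kPa, excurrent flow L/min)."""
    fr_i = spec.flow_lpm
    f_wi = spec.incurrent_wvp / spec.p_baro_kpa
    f_ci = AMBIENT_CO2_FRAC
    v_co2 = spec.true_vco2 / 1000.0
    v_h2o = spec.true_ewl / MG_WATER_PER_L_VAPOR
    v_o2 = v_co2 / spec.rq
    fr_e = fr_i + v_h2o + v_co2 - v_o2
    f_we = (fr_i * f_wi + v_h2o) / fr_e
    f_ce = (fr_i * f_ci + v_co2) / fr_e
    wvp_ss = f_we * spec.p_baro_kpa
    if wvp_ss >= svp(spec.t_set):
        raise InfeasibleHumidityError(
            f"steady-state vapor pressure {wvp_ss:.3f} kPa exceeds saturation "
            f"at {spec.t_set} °C — raise flow or lower true_ewl")
    return f_ce, wvp_ss, fr_e


def gen_respirometry_trace(spec: TrueTrialSpec,
                           seed: int | None = None) -> tuple[GasTrace, dict]:
    """Simulate one trial trace plus its truth record.

    The chamber starts at incurrent composition and relaxes
    exponentially (time constant V/FR_e) toward the steady state implied
    by the true gas exchange; the analyzer alternates baseline and
    sample lines (baseline first), sees everything delayed by ``lag_s``,
    and adds Gaussian sensor noise.
    """
    rng = np.random.default_rng(seed)
    f_ce, wvp_ss, fr_e = _steady_state(spec)
    f_ci = AMBIENT_CO2_FRAC
    wvp_in = spec.incurrent_wvp

    cycle = spec.baseline_s + spec.sample_s
    total = cycle * spec.n_cycles
    time = np.arange(0.0, total, spec.dt_s)
    tau_s = spec.chamber_volume_l / fr_e * 60.0

    relax = 1.0 - np.exp(-time / tau_s)
    chamber_co2 = f_ci + (f_ce - f_ci) * relax
    chamber_wvp = wvp_in + (wvp_ss - wvp_in) * relax

    in_cycle = np.mod(time, cycle)
    phase = np.where(in_cycle < spec.baseline_s,
                     Phase.BASELINE.value, Phase.SAMPLE.value)

    # analyzer reads its current line through the plumbing lag
    t_lag = np.clip(time - spec.lag_s, 0.0, None)
    seen_co2 = np.where(phase == Phase.SAMPLE.value,
                        np.interp(t_lag, time, chamber_co2), f_ci)
    seen_wvp = np.where(phase == Phase.SAMPLE.value,
                        np.interp(t_lag, time, chamber_wvp), wvp_in)

    co2 = np.clip(seen_co2 + rng.normal(0.0, spec.co2_noise_sd, time.size), 0.0, 0.05)
    wvp = np.clip(seen_wvp + rng.normal(0.0, spec.wvp_noise_sd, time.size),
                  0.0, svp(spec.t_set))

    trace = GasTrace(
        time=time, co2_frac=co2, wvp=wvp,
        flow_in=np.full(time.size, spec.flow_lpm),
        phase=phase,
        t_chamber=np.full(time.size, spec.t_set),
        p_baro=np.full(time.size, spec.p_baro_kpa))
    truth = {**asdict(spec), "steady_co2_frac": f_ce, "steady_wvp_kpa": wvp_ss,
             "excurrent_flow_lpm": fr_e, "tau_min": tau_s / 60.0, "seed": seed}
    return trace, truth


# -- bird populations ----------------------------------------------------

DESIGN_TEMPS = (15.0, 19.0, 23.0, 30.0, 32.0)


def gen_bird_population(model: ScholanderModel, n_birds: int = 13,
                        temps=DESIGN_TEMPS, seed: int | None = None,
                        treatment: str = "dry") -> tuple[pd.DataFrame, dict]:
    """Draw a records table from a known thermal-response model.

    Each bird gets a slope deviation b_i ~ Normal(0, sigma_slope); each
    observation adds segment-specific Gaussian noise.  Returns the
    records DataFrame (bird_id, treatment, t_set, vco2) and a truth dict
    holding the model parameters and per-bird slopes.
    """
    if n_birds < 2:
        raise ValueError("need at least 2 birds")
    rng = np.random.default_rng(seed)
    temps = np.asarray(temps, dtype=float)
    b = rng.normal(0.0, model.sigma_slope, n_birds)
    rows = []
    for i in range(n_birds):
        bird = f"bird{i + 1:02d}"
        x = np.minimum(temps - model.lct, 0.0)
        mean = model.plateau + (model.slope + b[i]) * x
        sd = np.where(temps < model.lct, model.sigma_below, model.sigma_above)
        y = mean + rng.normal(0.0, 1.0, temps.size) * sd
        for t, v in zip(temps, y):
            rows.append({"bird_id": bird, "treatment": treatment,
                         "t_set": t, "vco2": v})
    df = pd.DataFrame(rows)
    truth = {"model": asdict(model), "seed": seed,
             "slopes": {f"bird{i + 1:02d}": float(model.slope + b[i])
                        for i in range(n_birds)}}
    return df, truth


# -- weather -------------------------------------------------------------

@dataclass
class WeatherGenSpec:
    """Parameters of the phenomenological weather generator.

    Defaults emulate an Ames-like breeding season: daily means ramping
    ~10→24°C from Apr 1 to Jul 31, ±5.5°C diurnal swing, persistent
    AR(1) synoptic anomalies, humidity anticorrelated with the
    temperature anomaly, and clear-sky solar damped by slowly varying
    cloudiness.  With these values ≈65% of hours fall within 15–32°C.
    """

    years: tuple[int, ...] = (2023,)
    season_start: tuple[int, int] = (4, 1)
    season_end: tuple[int, int] = (7, 31)
    t_mean_start: float = 11.0      # °C daily mean at season start
    t_mean_end: float = 24.5        # at season end
    diurnal_amplitude: float = 5.5  # °C
    anomaly_sd: float = 3.5         # AR(1) stationary SD, °C
    anomaly_phi: float = 0.98       # hourly AR(1) coefficient
    rh_base: float = 72.0           # %
    rh_temp_coupling: float = 2.5   # % RH per °C of anomaly (negative coupling)
    rh_noise_sd: float = 6.0
    cloud_phi: float = 0.95
    clear_sky_max: float = 1000.0   # W/m² at zenith
    wind_log_mean: float = 1.2      # log m/s
    wind_log_sd: float = 0.5
    latitude: float = 42.106328
    longitude: float = -93.589807
    utc_offset: float = -6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal amplitude must be non-negative")
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude outside [-90, 90]")


def gen_weather(spec: WeatherGenSpec) -> pd.DataFrame:
    """Generate an hourly weather series (columns as read_weather emits)."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for year in spec.years:
        start = pd.Timestamp(year, *spec.season_start)
        end = pd.Timestamp(year, *spec.season_end) + pd.Timedelta(hours=23)
        ts = pd.date_range(start, end, freq="h")
        n = len(ts)
        frac = np.arange(n) / max(n - 1, 1)
        seasonal = spec.t_mean_start + (spec.t_mean_end - spec.t_mean_start) * frac
        hour = ts.hour.to_numpy()
        diurnal = spec.diurnal_amplitude * np.cos(2 * np.pi * (hour - 15) / 24.0)

        innov_sd = spec.anomaly_sd * np.sqrt(1.0 - spec.anomaly_phi ** 2)
        anom = np.empty(n)
        anom[0] = rng.normal(0.0, spec.anomaly_sd)
        shocks = rng.normal(0.0, innov_sd, n)
        for i in range(1, n):
            anom[i] = spec.anomaly_phi * anom[i - 1] + shocks[i]

        t_air = seasonal + diurnal + anom
        rh = np.clip(spec.rh_base - spec.rh_temp_coupling * (anom + diurnal)
                     + rng.normal(0.0, spec.rh_noise_sd, n), 5.0, 100.0)

        elev = solar_elevation(ts.to_numpy(), spec.latitude, spec.longitude,
                               spec.utc_offset)
        cloud = np.empty(n)
        cloud[0] = rng.normal(0.0, 1.0)
        c_shocks = rng.normal(0.0, np.sqrt(1 - spec.cloud_phi ** 2), n)
        for i in range(1, n):
            cloud[i] = spec.cloud_phi * cloud[i - 1] + c_shocks[i]
        transmittance = np.clip(0.75 - 0.35 * cloud, 0.15, 1.0)
        solar = spec.clear_sky_max * np.clip(np.sin(np.deg2rad(elev)), 0.0, None) \
            * transmittance

        wind = np.exp(rng.normal(spec.wind_log_mean, spec.wind_log_sd, n)) * 0.3
        frames.append(pd.DataFrame({
            "timestamp": ts, "t_air": t_air, "rh": rh,
            "solar": solar, "wind": wind}))
    return pd.concat(frames, ignore_index=True)


# -- spectra -------------------------------------------------------------

WAVELENGTH_GRID_NM = np.arange(350.0, 2003.0, 1.0)


def gen_reflectance(mean_level: float = 0.25, tilt: float = 0.0,
                    noise_sd: float = 0.0, seed: int | None = None) -> np.ndarray:
    """Smooth bounded reflectance spectrum on the 350–2002 nm 1-nm grid.

    ``tilt`` is the total reflectance change across the grid (positive =
    red/IR-brighter, as for dark melanized plumage); noise is smoothed
    with a ~50 nm kernel so the spectrum stays spectrally coherent.
    Returns an (N, 2) array of (wavelength_nm, reflectance).
    """
    if not 0.0 < mean_level < 1.0:
        raise ValueError("mean_level must lie in (0, 1)")
    wl = WAVELENGTH_GRID_NM
    centre = 0.5 * (wl[0] + wl[-1])
    refl = mean_level + tilt * (wl - centre) / (wl[-1] - wl[0])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = rng.normal(0.0, noise_sd, wl.size)
        kernel = np.exp(-0.5 * (np.arange(-75, 76) / 25.0) ** 2)
        kernel /= kernel.sum()
        refl = refl + np.convolve(raw, kernel, mode="same")
    return np.column_stack([wl, np.clip(refl, 1e-3, 1.0 - 1e-3)])


def gen_solar_irradiance() -> np.ndarray:
    """Synthetic smooth ground-level solar spectrum on the same grid.

    A 5778 K Planck curve scaled to ~1000 W m⁻² total — a stand-in for a
    measured reference irradiance spectrum with the same broad shape
    (visible peak, long IR tail); adequate for weighting reflectance.
    Returns (N, 2) of (wavelength_nm, W m⁻² nm⁻¹).
    """
    wl_m = WAVELENGTH_GRID_NM * 1e-9
    h, c, kb, t_sun = 6.626e-34, 2.998e8, 1.381e-23, 5778.0
    planck = (2 * h * c ** 2 / wl_m ** 5
              / (np.exp(h * c / (wl_m * kb * t_sun)) - 1.0))
    irr = planck / np.trapezoid(planck, WAVELENGTH_GRID_NM) * 1000.0
    return np.column_stack([WAVELENGTH_GRID_NM, irr])


# -- sidecar helpers -----------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float))
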