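"""Flow-through respirometry processing and humidity algebra.

Converts raw gas-analyzer traces (CO2 fraction, water vapor pressure, flow)
from a push-mode flow-through system into per-trial gas-exchange summaries:
CO2 production (V̇CO2, ml min⁻¹ STP), evaporative water loss (EWL,
mg H2O min⁻¹), and their energetic equivalents (metabolic heat production
MHP and evaporative heat loss EHL, W).

Conventions
-----------
* Flow rates are mass-flow-controller readings referenced to STP
  (0°C, 101.325 kPa); all temperatures are °C and pressures kPa.
* The pump sits upstream of the animal chamber (push system) and meters
  the *incurrent* air stream; excurrent flow is reconstructed from the
  gas added (water vapor, CO2) and removed (O2, via the respiratory
  exchange ratio) by the animal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("hygrotherm")

# -- physical constants --------------------------------------------------
STP_MOLAR_VOLUME_L = 22.414      # L per mol of ideal gas at 0°C, 101.325 kPa
WATER_MOLAR_MASS_G = 18.015      # g per mol
STP_PRESSURE_KPA = 101.325

# Mass of water vapor (mg) per liter of vapor at STP.
MG_WATER_PER_L_VAPOR = WATER_MOLAR_MASS_G / STP_MOLAR_VOLUME_L * 1000.0


class TraceError(ValueError):
    """Raised when a gas trace violates its physical invariants."""


class InfeasibleHumidityError(ValueError):
    """Requested vapor pressure exceeds saturation at that temperature."""


class NoStableWindowError(RuntimeError):
    """No window of the requested duration satisfied the stability criterion."""


class FlaggedRecordError(ValueError):
    """Gas exchange was negative beyond the rejection tolerance."""


# -- humidity algebra ----------------------------------------------------

def svp(t_air: float | np.ndarray) -> float | np.ndarray:
    """Saturation vapor pressure over liquid water (kPa).

    Uses the Buck (1981) ew1 formulation,
    ``0.61121 * exp(17.502*T / (240.97 + T))`` with T in °C.  Tetens and
    Magnus variants agree with it within ~0.5% over 0-40°C, well inside
    the tolerances used anywhere in this package.

    Parameters
    ----------
    t_air : float or array
        Air temperature, °C.  Valid range −40 to 60°C.
    """
    t = np.asarray(t_air, dtype=float)
    if np.any(t < -40.0) or np.any(t > 60.0):
        raise ValueError(f"temperature outside [-40, 60] °C: {t_air!r}")
    out = 0.61121 * np.exp(17.502 * t / (240.97 + t))
    return float(out) if np.isscalar(t_air) or out.ndim == 0 else out


def vpd(t_air: float, rh: float) -> float:
    """Vapor pressure deficit (kPa): ``SVP(T) * (1 - RH/100)``.

    The drying power of air controlling for temperature; ``rh`` is
    relative humidity in percent.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0.0) or np.any(rh_arr > 100.0):
        raise ValueError(f"relative humidity outside [0, 100] %: {rh!r}")
    return svp(t_air) * (1.0 - rh_arr / 100.0)


def rh_for_vpd(t_air: float, target_vpd: float) -> float:
    """Relative humidity (%) at ``t_air`` that produces ``target_vpd``.

    Exact inverse of :func:`vpd` in its RH argument.  Raises
    :class:`InfeasibleHumidityError` if the target deficit exceeds
    saturation vapor pressure at ``t_air`` (RH would be negative).
    """
    sat = svp(t_air)
    if target_vpd < 0:
        raise ValueError("target_vpd must be non-negative")
    if target_vpd > sat:
        raise InfeasibleHumidityError(
            f"VPD {target_vpd:.4g} kPa exceeds SVP {sat:.4g} kPa at {t_air} °C"
        )
    return 100.0 * (1.0 - target_vpd / sat)


def latent_heat_vaporization(t_c: float) -> float:
    """Latent heat of vaporization of water, J per mg, at ``t_c`` °C.

    Linear fit ``2.501 - 0.00237*T`` (kJ g⁻¹ ≡ J mg⁻¹), accurate to
    <0.1% over 0-50°C.
    """
    return 2.501 - 0.00237 * t_c


def oxyjoule_equivalent(rer: float) -> float:
    """Thermal equivalent of oxygen, kJ per L O2, as a function of RER.

    ``16 + 5.164*RER``; at RER = 0.71 (lipid oxidation in post-absorptive
    birds) this is 19.67 kJ L⁻¹.
    """
    return 16.0 + 5.164 * rer


# -- domain types --------------------------------------------------------

class Phase(str, Enum):
    BASELINE = "baseline"
    SAMPLE = "sample"


class WindowMethod(str, Enum):
    LOWEST_STABLE_MINUTE = "lowest_stable_minute"
    ASYMPTOTE = "asymptote"


TRACE_COLUMNS = [
    "time_s", "co2_frac", "wvp_kpa", "flow_lpm", "phase",
    "t_chamber_c", "p_baro_kpa",
]


@dataclass
class GasTrace:
    """Multichannel time series from one flow-through respirometry run.

    ``time`` is seconds from trial start (strictly increasing);
    ``co2_frac`` is the fractional CO2 concentration of the subsampled
    air (wet basis, unitless); ``wvp`` is water vapor pressure (kPa);
    ``flow_in`` is incurrent flow (L min⁻¹ STP); ``phase`` marks whether
    the analyzer was on the baseline or the animal (sample) line.
    """

    time: np.ndarray
    co2_frac: np.ndarray
    wvp: np.ndarray
    flow_in: np.ndarray
    phase: np.ndarray          # array of "baseline" / "sample"
    t_chamber: np.ndarray
    p_baro: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "co2_frac", "wvp", "flow_in", "t_chamber", "p_baro"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.phase = np.asarray(self.phase, dtype=object)
        self.validate()

    def validate(self, wvp_tolerance_kpa: float = 0.05) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise TraceError("time must be strictly increasing")
        if np.any(self.co2_frac < 0) or np.any(self.co2_frac > 0.05):
            raise TraceError("co2_frac outside [0, 0.05]")
        if np.any(self.wvp < 0):
            raise TraceError("negative water vapor pressure")
        if np.any(self.wvp > svp(self.t_chamber) + wvp_tolerance_kpa):
            raise TraceError("water vapor pressure exceeds saturation at chamber temperature")
        if np.any(self.flow_in <= 0):
            raise TraceError("flow_in must be positive")

    def __len__(self) -> int:
        return self.time.size

    def mask(self, phase: Phase | str) -> np.ndarray:
        return self.phase == str(Phase(phase).value)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GasTrace":
        df = pd.read_csv(path)
        missing = set(TRACE_COLUMNS) - set(df.columns)
        if missing:
            raise TraceError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(
            time=df["time_s"].to_numpy(),
            co2_frac=df["co2_frac"].to_numpy(),
            wvp=df["wvp_kpa"].to_numpy(),
            flow_in=df["flow_lpm"].to_numpy(),
            phase=df["phase"].to_numpy(),
            t_chamber=df["t_chamber_c"].to_numpy(),
            p_baro=df["p_baro_kpa"].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "time_s": self.time, "co2_frac": self.co2_frac,
            "wvp_kpa": self.wvp, "flow_lpm": self.flow_in,
            "phase": self.phase, "t_chamber_c": self.t_chamber,
            "p_baro_kpa": self.p_baro,
        }).to_csv(path, index=False)

    def replace(self, **channels: np.ndarray) -> "GasTrace":
        data = {
            "time": self.time, "co2_frac": self.co2_frac, "wvp": self.wvp,
            "flow_in": self.flow_in, "phase": self.phase,
            "t_chamber": self.t_chamber, "p_baro": self.p_baro,
        }
        data.update(channels)
        return GasTrace(**data)


@dataclass
class StableWindow:
    """A stretch of trace judged stable, summarized by its mean."""

    start: float
    end: float
    mean_value: float
    sd_value: float
    method: WindowMethod


@dataclass
class GasExchangeRecord:
    """One bird × temperature × treatment summary."""

    bird_id: str
    treatment: str                # "dry" or "humid"
    t_set: float                  # set-point temperature, °C
    vco2: float                   # ml CO2 min⁻¹ (STP)
    ewl: float                    # mg H2O min⁻¹
    vpd: float                    # chamber vapor pressure deficit, kPa
    ewl_vpd: float                # VPD-corrected EWL, mg min⁻¹ kPa⁻¹
    t_b: float                    # body temperature, °C
    ehl: float                    # evaporative heat loss, W
    mhp: float                    # metabolic heat production, W
    ehl_mhp: float                # evaporative cooling efficiency
    flags: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def records_to_csv(records: list[GasExchangeRecord], path: str | Path) -> None:
    """Write one row per record.  Units: see module docstring (STP flows,
    °C, kPa); documented here so every output file carries its own key."""
    df = pd.DataFrame([r.to_dict() for r in records])
    with open(path, "w") as fh:
        fh.write("# units: vco2 ml/min STP; ewl mg/min; vpd kPa; ehl,mhp W; temps degC\n")
        df.to_csv(fh, index=False)


def records_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- processing configuration -------------------------------------------

@dataclass
class ProcessingConfig:
    """Tunables for trace processing.

    ``tau_min`` is the first-order response time constant in minutes
    (chamber volume / flow rate: 1.8 L at 4 L min⁻¹ gives 0.45 min);
    ``lag_s`` is the fixed plumbing/analyzer delay in seconds.
    Stability = rolling SD ≤ ``rel_sd_threshold`` × |window mean| with no
    sample deviating more than ``spike_sd`` SDs from the window mean.
    """

    lag_s: float = 5.0
    tau_min: float = 0.45
    window_s: float = 60.0
    transient_s: float = 30.0   # discarded after each line switch
    smooth_s: float = 10.0      # boxcar for the derivative in the correction
    rel_sd_threshold: float = 0.02
    sd_floor_co2: float = 1e-5     # absolute stability floors: sensor-noise
    sd_floor_wvp: float = 0.008    # scale, where 2% of the mean is below noise
    spike_sd: float = 4.0
    rq: float = 0.71
    negative_tolerance: float = 0.02   # fraction of baseline level
    clamp_policy: str = "clamp"        # or "raise"
    latent_heat_at: str = "body"       # or "chamber"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProcessingConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# -- response correction -------------------------------------------------

def _boxcar(x: np.ndarray, t: np.ndarray, width_s: float) -> np.ndarray:
    dt = np.median(np.diff(t))
    n = max(1, int(round(width_s / dt)))
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    padded = np.r_[np.full(n, x[0]), x, np.full(n, x[-1])]
    return np.convolve(padded, kernel, mode="same")[n:-n]


def correct_response(trace: GasTrace, tau: float | None = None,
                     lag: float | None = None, smooth_s: float = 0.0,
                     config: ProcessingConfig | None = None) -> GasTrace:
    """Lag- and response-correct the gas channels of a trace.

    The analyzer sees the chamber through a delay ``lag`` (seconds) and a
    first-order washout with time constant ``tau`` (minutes).  The
    correction shifts each gas channel back by the lag and applies the
    instantaneous transform ``x_inst(t) = x(t) + tau * dx/dt``, which
    inverts the washout exactly for a well-mixed chamber; steady-state
    values are unchanged.  With ``smooth_s > 0`` (the pipeline passes
    ``config.smooth_s``) the derivative is estimated on a boxcar-smoothed
    copy of the channel, which tames the noise amplification inherent in
    the derivative term without touching steady-state levels.

    If the corrected trace turns negative over more than 5% of samples a
    warning is raised; negatives are clamped to zero under the default
    policy, or the trace is rejected when ``config.clamp_policy ==
    "raise"``.
    """
    config = config or ProcessingConfig()
    if tau is None:
        tau = config.tau_min
    if lag is None:
        lag = config.lag_s
    if tau < 0:
        raise ValueError("tau must be non-negative")
    tau_s = tau * 60.0

    t = trace.time
    out = {}
    for name in ("co2_frac", "wvp"):
        x = getattr(trace, name)
        if lag != 0:
            # reading at t describes the chamber at t - lag
            x = np.interp(t, t - lag, x)
        if tau_s > 0:
            base = _boxcar(x, t, smooth_s) if smooth_s > 0 else x
            x = x + tau_s * np.gradient(base, t)
        out[name] = x

    n_neg = sum(int(np.sum(v < 0)) for v in out.values())
    if n_neg > 0.05 * 2 * len(trace):
        msg = f"response correction produced {n_neg} negative samples (tau={tau} min)"
        if config.clamp_policy == "raise":
            raise TraceError(msg)
        warnings.warn(msg + "; clamping to zero")
    out = {k: np.clip(v, 0.0, None) for k, v in out.items()}
    # clamp CO2 to its physical ceiling so the corrected trace revalidates
    out["co2_frac"] = np.clip(out["co2_frac"], 0.0, 0.05)
    out["wvp"] = np.minimum(out["wvp"], svp(trace.t_chamber))
    return trace.replace(**out)


# -- stable-window selection --------------------------------------------

def find_stable_window(time: np.ndarray, values: np.ndarray,
                       duration: float = 60.0,
                       sd_threshold: float | None = None,
                       mode: WindowMethod | str = WindowMethod.LOWEST_STABLE_MINUTE,
                       rel_sd_threshold: float = 0.02,
                       sd_floor: float = 0.0,
                       spike_sd: float = 4.0) -> StableWindow:
    """Locate the stable stretch that summarizes a channel.

    ``lowest_stable_minute`` scans every contiguous window spanning at
    least ``duration`` seconds, keeps those whose SD is below the
    threshold (absolute ``sd_threshold`` if given, else
    ``rel_sd_threshold`` × |window mean| with the absolute floor
    ``sd_floor`` for channels whose mean sits near zero) and free of
    samples deviating
    more than ``spike_sd`` SDs from the window mean, and returns the one
    with the smallest mean.  ``asymptote`` instead fits
    ``a - b*exp(-t/tau)`` and reports the asymptote ``a`` — used for
    slow-responding water vapor readings.
    """
    mode = WindowMethod(mode)
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.size != values.size:
        raise ValueError("time and values must have the same length")
    span = time[-1] - time[0]
    if span < duration:
        raise ValueError("series shorter than requested window duration")

    if mode is WindowMethod.ASYMPTOTE:
        t0 = time - time[0]
        tau0 = max(span / 5.0, 1e-6)
        sign = 1.0 if values[-1] >= values[0] else -1.0
        p0 = [values[-1], sign * (values[-1] - values[0]), tau0]
        with warnings.catch_warnings():
            # near-flat series make b/tau unidentifiable; the asymptote is fine
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda t, a, b, tau: a - b * np.exp(-t / np.maximum(tau, 1e-9)),
                t0, values, p0=p0, maxfev=20000,
            )
        a, b, tau_fit = popt
        resid = values - (a - b * np.exp(-t0 / max(tau_fit, 1e-9)))
        return StableWindow(start=float(time[0]), end=float(time[-1]),
                            mean_value=float(a),
                            sd_value=float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0,
                            method=WindowMethod.ASYMPTOTE)

    # window length in samples for a (near-)uniform grid
    dt = np.median(np.diff(time))
    n_win = max(2, int(round(duration / dt)))
    best: StableWindow | None = None
    for i in range(0, time.size - n_win + 1):
        w = values[i:i + n_win]
        mean = float(np.mean(w))
        sd = float(np.std(w, ddof=1))
        thresh = (sd_threshold if sd_threshold is not None
                  else max(rel_sd_threshold * abs(mean), sd_floor))
        if sd > thresh:
            continue
        if sd > 0 and np.max(np.abs(w - mean)) > spike_sd * sd:
            continue
        if best is None or mean < best.mean_value:
            best = StableWindow(start=float(time[i]), end=float(time[i + n_win - 1]),
                                mean_value=mean, sd_value=sd,
                                method=WindowMethod.LOWEST_STABLE_MINUTE)
    if best is None:
        raise NoStableWindowError(
            f"no {duration:.0f}-s window met the stability criterion"
        )
    return best


# -- steady-state mass balance ------------------------------------------

def compute_gas_exchange(sample_co2: StableWindow | float,
                         baseline_co2: StableWindow | float,
                         sample_wvp: StableWindow | float,
                         baseline_wvp: StableWindow | float,
                         flow_lpm: float, p_baro_kpa: float,
                         rq: float = 0.71,
                         negative_tolerance: float = 0.02) -> tuple[float, float, str]:
    """Steady-state mass balance for a push flow-through system.

    Measured wet-basis fractions (CO2 fraction directly; water vapor as
    ``wvp / P_baro``) enter a two-gas balance in which the excurrent flow
    is reconstructed from the animal's gas exchange::

        FR_e = FR_i + V̇H2O + V̇CO2·(1 − 1/RQ)
        FR_e·F_we = FR_i·F_wi + V̇H2O
        FR_e·F_ce = FR_i·F_ci + V̇CO2

    which is linear in (V̇H2O, V̇CO2) and solved exactly; this is
    algebraically equivalent to water-vapor-dilution ("mathematical
    scrubbing") corrections followed by the standard textbook equations.

    Returns ``(vco2 ml min⁻¹ STP, ewl mg min⁻¹, flags)``.  Sample
    concentrations slightly below baseline (within ``negative_tolerance``
    of the baseline level) are clamped to zero exchange and flagged;
    larger deficits raise :class:`FlaggedRecordError`.
    """
    if not 0.7 <= rq <= 1.0:
        raise ValueError("rq must lie in [0.7, 1.0]")

    def _mean(w):
        return w.mean_value if isinstance(w, StableWindow) else float(w)

    f_ce = _mean(sample_co2)
    f_ci = _mean(baseline_co2)
    f_we = _mean(sample_wvp) / p_baro_kpa
    f_wi = _mean(baseline_wvp) / p_baro_kpa

    flags = []
    f_ce, flag = _apply_negative_policy(f_ce, f_ci, negative_tolerance, "co2")
    if flag:
        flags.append(flag)
    f_we, flag = _apply_negative_policy(f_we, f_wi, negative_tolerance, "h2o")
    if flag:
        flags.append(flag)

    k = 1.0 - 1.0 / rq
    # rows: water balance, CO2 balance; unknowns (vdot_h2o, vdot_co2) in L/min
    a = np.array([[f_we - 1.0, k * f_we],
                  [f_ce, k * f_ce - 1.0]])
    b = np.array([flow_lpm * (f_wi - f_we), flow_lpm * (f_ci - f_ce)])
    vdot_h2o, vdot_co2 = np.linalg.solve(a, b)

    vco2_ml = max(vdot_co2, 0.0) * 1000.0
    ewl_mg = max(vdot_h2o, 0.0) * MG_WATER_PER_L_VAPOR
    return vco2_ml, ewl_mg, ";".join(flags)


def _apply_negative_policy(sample: float, baseline: float, tol: float,
                           channel: str) -> tuple[float, str]:
    if sample >= baseline:
        return sample, ""
    deficit = baseline - sample
    if baseline > 0 and deficit <= tol * baseline:
        return baseline, f"{channel}_clamped"
    raise FlaggedRecordError(
        f"{channel} sample below baseline by {deficit:.3g} "
        f"(> {tol:.0%} of baseline)"
    )


def energy_partition(vco2: float, ewl: float, rer: float = 0.71,
                     t_evap: float = 40.0) -> tuple[float, float, float]:
    """Convert gas exchange to heat fluxes.

    MHP (W) = (V̇CO2/RER) ml O2 min⁻¹ × q(RER) J ml⁻¹ / 60, with the
    oxy-joule equivalent q(RER) = 16 + 5.164·RER kJ L⁻¹ O2.
    EHL (W) = EWL mg min⁻¹ × λ(t_evap) J mg⁻¹ / 60, with λ the latent
    heat of vaporization at the evaporating-surface temperature
    (body temperature by default).  Returns ``(mhp, ehl, ehl/mhp)``.
    """
    if rer <= 0:
        raise ValueError("rer must be positive")
    if vco2 < 0 or ewl < 0:
        raise ValueError("vco2 and ewl must be non-negative")
    if vco2 == 0:
        raise ZeroDivisionError("EHL/MHP undefined at vco2 = 0")
    vo2_ml_min = vco2 / rer
    mhp = vo2_ml_min * oxyjoule_equivalent(rer) / 60.0
    ehl = ewl * latent_heat_vaporization(t_evap) / 60.0
    return mhp, ehl, ehl / mhp


# -- full-trace pipeline -------------------------------------------------

def _trim_segments(time: np.ndarray, mask: np.ndarray, transient_s: float,
                   end_trim_s: float | None = None) -> np.ndarray:
    """Drop samples near each segment edge.

    Line switching produces spikes (plumbing lag plus the derivative
    term of the response correction, which a centered smoother spreads a
    little way into both neighbouring segments) that are not chamber
    signal; ``transient_s`` is cut from each segment start and
    ``end_trim_s`` (default: the same) from each end.
    """
    if transient_s <= 0 and not end_trim_s:
        return mask
    if end_trim_s is None:
        end_trim_s = transient_s
    out = mask.copy()
    edges = np.flatnonzero(np.diff(np.r_[False, mask, False]))
    for s, e in zip(edges[::2], edges[1::2]):     # [s, e) is one segment
        seg_t = time[s:e]
        keep = (seg_t >= seg_t[0] + transient_s) & (seg_t <= seg_t[-1] - end_trim_s)
        out[s:e] &= keep
    return out

@dataclass
class TrialInfo:
    """Metadata for one respirometry trial (one bird at one set point)."""

    bird_id: str
    treatment: str
    t_set: float
    t_b: float = 41.0
    mass_g: float = 18.9


def process_trace(trace: GasTrace, trial: TrialInfo,
                  config: ProcessingConfig | None = None) -> GasExchangeRecord:
    """Raw trace → :class:`GasExchangeRecord`.

    Applies response correction, picks stable windows on the baseline and
    sample segments of each gas channel (lowest-stable-minute; the slower
    water channel falls back to an asymptote fit when no window
    stabilizes), runs the
    mass balance, computes the chamber VPD from incurrent humidity, and
    partitions energy at RER ``config.rq``.
    """
    config = config or ProcessingConfig()
    corrected = correct_response(trace, smooth_s=config.smooth_s, config=config)

    base = _trim_segments(corrected.time, corrected.mask(Phase.BASELINE),
                          config.transient_s)
    samp = _trim_segments(corrected.time, corrected.mask(Phase.SAMPLE),
                          config.transient_s)
    if not base.any() or not samp.any():
        raise TraceError("trace needs both baseline and sample phases")

    def _window(mask, channel, mode):
        floor = config.sd_floor_co2 if channel == "co2_frac" else config.sd_floor_wvp
        return find_stable_window(
            corrected.time[mask], getattr(corrected, channel)[mask],
            duration=config.window_s, mode=mode,
            rel_sd_threshold=config.rel_sd_threshold, sd_floor=floor,
            spike_sd=config.spike_sd)

    w_co2_b = _window(base, "co2_frac", WindowMethod.LOWEST_STABLE_MINUTE)
    w_co2_s = _window(samp, "co2_frac", WindowMethod.LOWEST_STABLE_MINUTE)
    w_wvp_b = _window(base, "wvp", WindowMethod.LOWEST_STABLE_MINUTE)
    try:
        # water channel: stable-minute average when one exists ...
        w_wvp_s = _window(samp, "wvp", WindowMethod.LOWEST_STABLE_MINUTE)
    except NoStableWindowError:
        # ... else fit the asymptote of the slow-stabilizing reading
        w_wvp_s = _window(samp, "wvp", WindowMethod.ASYMPTOTE)

    flow = float(np.mean(corrected.flow_in))
    p_baro = float(np.mean(corrected.p_baro))
    vco2, ewl, flags = compute_gas_exchange(
        w_co2_s, w_co2_b, w_wvp_s, w_wvp_b, flow, p_baro,
        rq=config.rq, negative_tolerance=config.negative_tolerance)

    chamber_vpd = max(float(svp(trial.t_set)) - w_wvp_b.mean_value, 0.0)
    t_evap = trial.t_b if config.latent_heat_at == "body" else trial.t_set
    if vco2 > 0:
        mhp, ehl, ratio = energy_partition(vco2, ewl, rer=config.rq, t_evap=t_evap)
    else:
        mhp = ehl = ratio = float("nan")
        flags = (flags + ";zero_vco2").strip(";")

    return GasExchangeRecord(
        bird_id=trial.bird_id, treatment=trial.treatment, t_set=trial.t_set,
        vco2=vco2, ewl=ewl, vpd=chamber_vpd,
        ewl_vpd=ewl / chamber_vpd if chamber_vpd > 0 else float("nan"),
        t_b=trial.t_b, ehl=ehl, mhp=mhp, ehl_mhp=ratio, flags=flags)
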