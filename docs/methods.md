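# Methods

This note documents the models implemented in `hygrotherm`, the
numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate about real data.

## Humidity algebra

Saturation vapor pressure uses Buck's (1981) liquid-water formulation,
`SVP(T) = 0.61121·exp(17.502·T/(240.97+T))` kPa, valid −40 to 60 °C.
Tetens/Magnus variants agree within ~0.5% over 0–40 °C, which is far
inside every tolerance used here; the choice is therefore one of
convention, and it reproduces the standard worked example (dry air at
10 °C has a deficit of 1.228 kPa, matched at 32 °C by 74.2% relative
humidity). Vapor pressure deficit is `SVP·(1 − RH/100)`, and
`rh_for_vpd` inverts it exactly, raising an error when the requested
deficit exceeds saturation.

## Respirometry processing

**System model.** A push system: a mass-flow controller meters incurrent
air (STP reference: 0 °C, 101.325 kPa) into a 1.8 L chamber at
4 L min⁻¹; the analyzer subsamples the excurrent line and is switched
manually between it and a baseline (incurrent) line. The chamber is
treated as a single well-mixed compartment, so gas concentrations relax
first-order with time constant τ = V/FR (0.45 min at the default
volume and flow), and the analyzer sees everything through a fixed
plumbing lag.

**Response correction.** Channels are shifted back by the configured lag
and sharpened with the instantaneous transform
`x_inst(t) = x(t) + τ·dx/dt`, which inverts the washout exactly for a
well-mixed chamber and leaves steady states untouched. The derivative
amplifies sensor noise, so the pipeline estimates it on a
boxcar-smoothed copy (default 10 s) — steady-state levels are
unaffected, and band-limited signals round-trip through
filter-then-correct with <2% L2 error. A fixed configured lag is used
rather than cross-correlation estimation: it matches how commercial
acquisition software is normally operated and is deterministic.

**Stable windows.** A window qualifies as stable when its SD is below
max(2% of the window mean, an absolute floor) and no sample deviates
more than 4 SD from the window mean (the spike rule). The absolute
floors (1e-5 CO2 fraction, 0.008 kPa water) exist because a purely
relative criterion is unsatisfiable on channels whose mean sits at the
sensor-noise floor — the dry-air baseline water channel reads
~0.004 kPa with ~0.002 kPa noise. CO2 and baselines use the
lowest-stable-minute rule (the qualifying window with the smallest
mean); the slower water channel on the animal line uses the same rule
when a window qualifies and otherwise falls back to fitting
`a − b·exp(−t/τ)` and reporting the asymptote `a`. The first and last
30 s of every line segment are discarded: switching transients (lag
plus the spread of the derivative term across the switch) are plumbing
artifacts, not chamber signal.

**Mass balance.** With wet-basis fractions (CO2 read directly; water as
WVP/P_baro), the excurrent flow is reconstructed from what the animal
adds and removes:

    FR_e = FR_i + V̇H2O + V̇CO2·(1 − 1/RQ)
    FR_e·F_we = FR_i·F_wi + V̇H2O
    FR_e·F_ce = FR_i·F_ci + V̇CO2

This 2×2 linear system is solved exactly; it is algebraically
equivalent to the usual "mathematically scrubbed" dilution-corrected
textbook equations but avoids their one-step approximation, which is
why closed-loop tests recover injected truth to machine precision in
the noise-free case. RQ defaults to 0.71 (post-absorptive, lipid
oxidation). Sample readings below baseline within 2% of the baseline
level are clamped to zero exchange and flagged; larger deficits are
rejected outright.

**Energy partition.** MHP = (V̇CO2/RER)·q(RER)/60 W with the oxy-joule
equivalent q(RER) = 16 + 5.164·RER kJ per L O2; EHL = EWL·λ(T)/60 W
with λ(T) = 2.501 − 0.00237·T J mg⁻¹ evaluated at body temperature by
default (configurable to chamber temperature — the evaporating surface
lies between the two; the difference is <1% over the plausible range).

## Segmented thermal-response model

The population curve is continuous at the breakpoint by construction:
mean = plateau for t ≥ LCT and plateau + slope·(t − LCT) below it.
Each bird deviates in slope only (bᵢ ~ Normal(0, σ_slope)); residual
SDs are segment-specific. Because bᵢ enters linearly, each bird's
observations are jointly Gaussian with covariance D + σ_slope²·xxᵀ
(x = min(t − LCT, 0)), inverted in closed form via Sherman–Morrison.
The marginal likelihood is therefore exact — no Monte-Carlo
marginalization is needed, and the likelihood is invariant to row order
and bird relabeling by construction.

**Priors** (weakly informative, all configurable): LCT uniform over the
observed temperature range; slope Normal(0, 0.5) — the sign is *not*
constrained, so a negative posterior slope is evidence, not assumption;
plateau Normal centred on the mean of observations ≥28 °C with a 10×SD
scale; residual SDs half-Normal(1.0); σ_slope half-Normal(0.1). Mass
and sex are deliberately absent from the default model.

**Fitting.**
* `mcmc` (default): affine-invariant ensemble sampler, 32 walkers ×
  2500 steps (1000 burn-in, thinned ×2), seeded and bit-reproducible.
  Point estimates are posterior means; intervals are 2.5/97.5
  percentiles. Diagnostics: split-chain R̂ per parameter (threshold
  1.1), effective sample size from the integrated autocorrelation time,
  acceptance fraction, and the local modes of the LCT histogram (so a
  multimodal breakpoint posterior is visible rather than silently
  averaged). Non-convergence flags the result but still returns it.
* `profile`: maximum *penalized* likelihood (the same priors) over an
  LCT grid (0.25 °C), warm-started, followed by a continuous six-
  parameter polish; the LCT interval comes from the profile deviance
  (χ²₁ cutoff) and the remaining intervals are Wald (log-scale for
  SDs). The penalty matters: the unpenalized mixed-model likelihood is
  unbounded as a residual SD → 0, and the grid is restricted to
  breakpoints with ≥2 distinct temperatures on each side, which is the
  identifiability boundary of a two-segment model. Known behavior: the
  MAP of σ_slope can collapse to zero when it is weakly identified;
  the MCMC posterior mean does not, which is one reason mcmc is the
  default and the two modes are only required to agree on LCT, slope
  and plateau (within 5% on well-conditioned data, verified in tests).

Simulation calibration (100 cohorts of 13 birds × 5 temperatures at
realistic noise): 95% intervals cover the true LCT in 92% and the true
slope in 94% of cohorts; the mean LCT estimate at 26 birds is within
0.2 °C of truth.

**Prediction.** `predict_vco2` returns the deterministic curve value or
adds Normal noise with the requested segment's SD, truncated at zero by
redrawing — matching how the field simulation consumes the fit.

## Biophysical model

The bird is an insulated sphere: a core of diameter
`characteristic_length` at body temperature T_b, wrapped in a plumage
shell of depth d̄ (dorsal/ventral depths averaged 50/50 by default).
All traits come from configurable power laws a·mass^b with
order-of-magnitude passerine defaults (for 18.9 g: body diameter
26.6 mm, plumage 3.6/2.7 mm dorsal/ventral). The defaults are
literature-style, not fitted to any particular dataset — the model's
purpose is the *procedure* (lab curve → T_es mapping), and every
constant is exposed in `BiophysConfig`.

Steady-state surface balance, solved for the outer coat temperature
T_s by bracketed root-finding (tolerance 1e-10 °C):

    K_p·(T_b − T_s) = K_c·(T_s − T_air) + εσA·(T_s⁴ − T_rad⁴) − S_abs

* K_p: spherical-shell coat conductance 4πk_f·r_b·r_o/d̄ with feather
  conductivity k_f = 0.027 W m⁻¹ K⁻¹ (still air within the coat plus
  keratin).
* K_c: Ranz–Marshall sphere correlation Nu = 2 + 0.6·Re^½·Pr^⅓ with
  temperature-dependent air properties; wind is floored at a reference
  0.1 m s⁻¹ representing free convection.
* Radiation: grey body, emissivity 0.95.
* S_abs: absorptance × irradiance × area × (0.5·(1−f_d) + f_d), i.e.
  beam on half the surface and isotropic diffuse (fraction f_d = 0.15)
  on all of it. Absorptance is 1 minus the solar-weighted reflectance,
  trapezoid-integrated on the union wavelength grid (the measurement
  convention is 1-nm resolution, 350–2002 nm).

Required metabolic heat is the dry loss through the coat plus the
evaporative term EWL·λ(T_b)/60; by construction the component fluxes
sum to it within solver tolerance (verified to <1 µW on 1000 random
scenarios).

**Standard operative temperature.** T_es is the air temperature of a
calm (reference-wind), dark, uniform enclosure at which the bird's dry
heat loss equals its dry loss in the field environment — the quantity
that lets chamber-measured curves be evaluated under field conditions.
It is found by a second bracketed root solve over [−40, 60] °C and is
exactly the air temperature for a calm/dark/uniform input. For long
weather series `OperativeTemperatureSolver` replaces the nested root
solves with a precomputed chamber curve (0.25 °C grid, interpolated
inverse) and vectorized Newton iteration for T_s; it matches the exact
solver to <0.01 °C and makes a decade of hourly weather take
milliseconds rather than minutes.

Body temperature follows the field schedule: 43 °C while the sun is up,
39 °C at night, switched on solar elevation computed from standard
solar-position geometry (Fourier-fit declination and equation of time;
accurate to a small fraction of a degree, ample for a day/night switch
and clear-sky shaping).

## Field simulation

For every breeding-season hour (Apr 1 – Jul 31) whose **air
temperature** lies in 15–32 °C — the span of the laboratory design, so
the fitted curves are never extrapolated — the simulation computes
T_es, then draws one resting V̇CO2 per physiology (dry and humid) from
the corresponding fitted curve with the residual SD of whichever
segment T_es falls in. Choices worth stating:

* The inclusion filter applies to air temperature, not T_es (the
  published 65% inclusion figure refers to weather observations); a
  config switch selects T_es filtering instead.
* One draw per hour per physiology, paired on the hour — mirroring the
  paired Wilcoxon design; medians are mass-specific
  (ml CO2 g⁻¹ h⁻¹ = ml min⁻¹ × 60/mass).
* Percent difference is (humid − dry)/dry × 100 — the only convention
  consistent with the printed median pair (0.860, 0.925 → 7.6%).
* Timestamps are local *standard* time with a configurable UTC offset
  and no daylight-saving shift, matching weather-station logging.
* The Wilcoxon signed-rank test drops zero differences, average-ranks
  ties, enumerates the exact null by dynamic programming for n ≤ 25,
  and uses a tie-corrected normal approximation with continuity
  correction above (the two agree within 0.01 at the crossover, and
  the exact mode matches brute-force sign enumeration and an
  independent reference implementation in tests).

With both residual SDs zero the simulation is fully deterministic and
seed-invariant; with noise it is bit-reproducible under a fixed seed.

## Synthetic data: what it emulates, and what it does not

* **Traces** follow exactly the physics the processor assumes
  (well-mixed washout, fixed lag, Gaussian sensor noise, alternating
  5-min baseline / 10-min sample phases). Closed-loop recovery within
  1% therefore validates the *implementation* — corrections, window
  logic, mass balance — not the adequacy of the single-compartment
  assumption for a real chamber with imperfect mixing, drifting
  baselines, or an active bird.
* **Populations** are drawn from the fitted model family itself, so
  coverage results certify calibration of the inference, not
  correctness of the segmented-Gaussian description of real birds.
* **Weather** is phenomenological: a seasonal ramp (daily means
  11 → 24.5 °C across the season) plus a 5.5 °C diurnal cosine and
  persistent AR(1) anomalies (SD 3.5 °C, hourly coefficient 0.98);
  humidity is anticorrelated with the temperature anomaly; solar is a
  clear-sky elevation curve damped by slowly varying cloudiness; wind
  is log-normal. The climatology constants were set in one seeded
  calibration pass so that the expected fraction of season hours inside
  15–32 °C is 0.65 ± 0.02 — the published inclusion fraction for the
  on-site station — because that fraction controls how much of the
  rising limb of the curves the simulation samples. The generator does
  not model fronts, precipitation, or humidity saturation dynamics.
* **Spectra**: reflectance is a smooth tilted line with spectrally
  coherent noise on the 350–2002 nm grid; the weighting irradiance is a
  synthetic 5778 K Planck curve scaled to ~1000 W m⁻² (a stand-in with
  the right broad shape for a measured reference spectrum — adequate
  for weighting, not for radiative-transfer work).

Absolute simulated medians depend on the thermoneutral plateau, which
published breakpoint fits do not report; the default models therefore
set a typical resting plateau (0.62 ml CO2 min⁻¹, ≈0.87 ml O2 min⁻¹ at
RER 0.71) with the humid plateau 2% above dry, matching the observed
within-TNZ elevation. The humid-vs-dry *relative* contrast — direction,
significance, and stability across seeds — is the supported claim; the
absolute level is not.

## Problem sizes and determinism in the test suite

The suite regenerates every fixture at run time. Sizes were chosen to
keep the full run under ~5 minutes on one CPU: the coverage study uses
100 cohorts of 13 birds (MCMC) plus 10 cohorts of 26 birds (profile);
the field-contrast stability check uses 20 seeds over one synthetic
season; energy conservation uses 1000 random scenarios; weather
calibration is checked on ten synthetic seasons. Every stochastic test
fixes its seeds; hypothesis property tests run derandomized.

## Known limitations

* Steady-state heat balance only: no heat storage, posture, or
  microsite selection; resting costs only, no activity or flight.
* The insulated-sphere geometry and its default constants are a
  committed convention, not a fitted morphology; conclusions that
  depend on absolute T_es values (rather than their ordering) should
  treat those constants as uncertain.
* No upper critical temperature: the model family has a single
  breakpoint and is not meant for data extending into heat stress.
* O2 is not measured; energetics rest on the assumed RER.
* The segmented model omits mass and sex by design; random effects are
  slopes only (no per-bird plateau deviation).
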