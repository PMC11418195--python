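# hygrotherm

Humidity effects on songbird thermoregulatory energetics: a tested,
reusable pipeline from raw flow-through respirometry traces to simulated
field resting costs.

Laboratory Scholander–Irving curves — resting metabolic rate flat on a
thermoneutral plateau and rising linearly below a lower critical
temperature (LCT) — are almost always measured in dry air, although wild
birds rarely experience it. This package implements the full analysis
chain needed to ask what humidity does to those curves and what it costs
in the field, built around tree swallows (*Tachycineta bicolor*,
~19 g aerial insectivores whose cold-wet-weather energetics drive adult
mortality and nest failure):

1. **`gas_exchange`** — turns time-stamped gas-analyzer traces (CO2
   fraction, water vapor pressure, flow) from a push-mode flow-through
   system into per-trial V̇CO2 (ml min⁻¹ STP), evaporative water loss
   (EWL, mg min⁻¹), vapor pressure deficit (VPD), and energy partitions
   (metabolic heat production MHP, evaporative heat loss EHL, in W).
   Includes lag + first-order response correction, stable-window
   selection, and an exact steady-state mass balance.
2. **`scholander`** — fits the segmented thermal-response model

       V̇CO2(t) ~ Normal( plateau + (slope + bᵢ)·min(t − LCT, 0), σ_segment ),
       bᵢ ~ Normal(0, σ_slope)

   with per-bird random slopes marginalized analytically; MCMC
   (ensemble sampler) or penalized-profile fitting, 95% intervals and
   convergence diagnostics.
3. **`biophys`** — an insulated-sphere heat-balance model (allometric
   morphology, solar-weighted plumage absorptance, plumage conductance
   in series with wind-dependent convection, grey-body radiation) that
   maps weather onto standard operative temperature T_es, the chamber
   temperature producing the same dry heat loss.
4. **`field_sim`** — drives the biophysical model with hourly weather,
   draws resting V̇CO2 from the fitted dry and humid curves at each
   hour's T_es, and compares the paired distributions (medians, percent
   difference, Wilcoxon signed-rank with exact small-n enumeration).
5. **`synthetic`** — generators for every input (chamber traces with
   first-order washout, bird populations from a known curve, Iowa-like
   breeding-season weather, reflectance spectra), each with a truth
   sidecar so every stage has a closed-loop test.

## Worked example

```python
import hygrotherm as hg
from hygrotherm.synthetic import WeatherGenSpec, gen_weather, tree_swallow_models

dry, humid = tree_swallow_models()        # published slopes/LCTs, 2% plateau gap
weather = gen_weather(WeatherGenSpec(years=(2022, 2023), seed=5))
morph = hg.allometry(18.9)                # 18.9 g swallow
optics = hg.PlumageOptics(0.84, 0.80)     # dorsal/ventral solar absorptance
res = hg.simulate_resting_costs(weather, dry, humid, morph, optics,
                                hg.SimConfig(seed=11))
print(res.summary())
```

prints

```
included 3996 h (68.2% of input); median resting V.CO2 dry 2.613, humid 2.887 ml CO2 g^-1 h^-1 (+10.5%); Wilcoxon W+=6869583, p=0
```

Reading: of two synthetic breeding seasons of hourly weather, 68% of
hours fell inside the 15–32°C range the laboratory curves cover; at
those hours the humid-physiology curve (higher LCT, slightly steeper
slope, 2% higher plateau) yields a median resting cost ~10% above the
dry-physiology curve, and the paired test says the shift is systematic.
Absolute medians depend on the assumed thermoneutral plateau, which is
study-specific; the relative contrast is the robust quantity.

The same steps are scriptable from the shell:

```sh
hygrotherm simulate weather --seed 3 --out sim/
hygrotherm fit --records records.csv --treatment dry --mode mcmc --seed 1 --out dry.json
hygrotherm field-sim --weather sim/weather.csv --model-dry dry.json \
    --model-humid humid.json --seed 3 --out result.json
```

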