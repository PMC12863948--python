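# pulsedose

Digesta-kinetics analysis for pulse-dosed external markers in grazing
cattle: fit the two-compartment, age-dependent/age-independent
marker-excretion model to per-animal fecal alkane time series, derive
fecal output by dilution of the dose, gut fill, residence times,
dry-matter intake, and grazing energetics — and generate synthetic trials
with known truth so every stage is verifiable without field data.

## Who this is for

Range and animal scientists estimating forage intake of free-ranging
cattle with a single pulse dose of an indigestible marker (here the C32
n-alkane dotriacontane, dosed as alkane-impregnated paper boluses). The
animal is gathered once, dosed, and fecal grab samples over the next four
days trace a single-peaked marker excretion curve whose shape carries the
kinetics of digesta flow.

## The model

Marker transit is modelled as a gamma-2 (age-dependent) mixing compartment
draining into an exponential (age-independent) mixing compartment followed
by a pure tubular delay, `G2(λ₁) → G1(k₂) → τ → feces`. With `u = t − τ`
and `δ = λ₁/(λ₁ − k₂)` the fecal marker concentration is

```
C(t) = C₂ δ² [ e^(−k₂u) − (1 + (λ₁ − k₂)u) e^(−λ₁u) ],   u > 0
```

and zero before the delay. The four parameters per animal-period are
`λ₁` (escape rate from the first compartment, /h), `k₂` (rumen passage
rate, /h, capped at 0.061 for rangeland fits), `τ` (transit delay, h) and
`C₂` (concentration scale, mg/kg fecal DM). Closed forms follow directly:

- area under the curve `AUC = C₂/k₂`;
- fecal DM output by dose dilution `FO = 24·D·k₂/C₂` (kg/d, dose D in mg);
- residence times `MCRT1 = 1/k₂`, `MCRT2 = 2/λ₁`,
  total-tract `RTG = 2/λ₁ + 1/k₂ + τ`;
- compartment masses `CM2 = D/C₂`, `CM1 = (FO/24)·2/λ₁`, fill
  `CMS = CM1 + CM2`.

Downstream, fecal-NIRS digestible organic matter (DOM) gives
`TDN = DOM × 1.05`, `ME = DOM × 4.6 × 0.82` Mcal/kg OM,
`DMI = FO/(1 − TDN)`, percent-of-BW intake, energy intake per kg^0.75,
harvest efficiency and harvest rate.

## Worked example

```python
import numpy as np
from pulsedose import (MarkerCurveModel, MarkerCurveParams, MarkerDose,
                       FecalSeries, excretion_concentration)

dose = MarkerDose.from_boluses(6, 756.0)          # 4536 mg C32 alkane
true = MarkerCurveParams(lambda1=0.33, k2=0.055, tau=12.8, c2=1003.0)
t = np.linspace(15, 90, 14)                        # h since dose
series = FecalSeries.from_arrays(t, excretion_concentration(t, true), dose)

res = MarkerCurveModel(series).fit()
print(res.summary())
d = res.derive(ash_fraction=0.212)                 # ash capped at 15%
print(f"FO {d.fo_dm:.2f} kg DM/d   RTG {d.rtg:.1f} h   fill {d.cms:.2f} kg")
```

prints

```
Marker excretion curve fit (G2 -> G1 -> delay)
===============================================
animal: -   period: -
n used: 14   deleted: 0   starts: 180
-----------------------------------------------
lambda1 (age-dependent rate, /h)       0.3300
k2      (passage rate, /h)             0.0550
tau     (transit delay, h)              12.80
C2      (scale conc, mg/kg DM)         1003.0
-----------------------------------------------
SSE         0.00   MSE         0.00 (mg/kg)^2
peak time     23.4 h post-dose
FO 5.97 kg DM/d   RTG 37.0 h   fill 6.03 kg
```

The fitted passage rate 0.055/h means a 18.2 h mean residence in the
slower compartment; dose dilution turns the fitted concentration scale
into 5.97 kg/d of fecal DM, and with ~62% digestibility that animal eats
roughly 16 kg DM/d.

A full synthetic trial (24 cows × two periods, the field sampling
schedule, 4.11% assay CV) runs end-to-end from the shell:

```
pulsedose all --seed 7 --out run7
```

which writes per-animal `fits.csv`, `derived.csv`, `intake.csv`, a
treatment × period `group_summary.csv`/`.txt`, and a `run_log.jsonl`
echoing every threshold and deleted sample.

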