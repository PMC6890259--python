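# adipoflux

Kinetic modelling of postprandial abdominal subcutaneous adipose tissue
metabolism from arteriovenous (A-V) meal-challenge data.

## The problem

During a mixed-meal challenge, simultaneous sampling of arterial blood and
the vein draining the abdominal subcutaneous adipose tissue, together with
adipose tissue blood flow (ATBF), yields metabolite *fluxes* across the
depot: flux = (arterial − venous) × ATBF, in µmol/(100 ml tissue·min),
positive for net uptake.  A [U-¹³C]palmitate meal tracer additionally
quantifies the fraction of lipoprotein-lipase (LPL)-derived fatty acids
that "spill over" into plasma instead of entering the tissue.

`adipoflux` implements a two-compartment (plasma + lumped interstitial
adipose) ODE model of these fluxes under delayed insulin control, and the
complete workflow around it: flux observables, weighted least-squares
parameter estimation with global search, Jacobian confidence intervals,
profile-likelihood identifiability analysis, AICc selection among
candidate rate laws, decomposition of net fluxes into constituent
reactions, and a synthetic cohort generator that emulates the 16-subject,
7-time-point (−30, 0, 60, 120, 180, 240, 300 min) A-V sampling design so
the whole pipeline is testable without access to clinical data.

## The model

Arterial concentrations ([I], [G], [TG], [GLY], [NEFA]) are exogenous
forcings.  Insulin acts through two three-compartment delay chains
(d[I₁]/dt = ([I_art] − [I₁])/τ, …), a slow one for LPL (τ_LPL) and a fast
one for the adipose compartment (τ_AT).  The flux terms:

- **LPL lipolysis**  TG_flux = K_ad·[TG_art]·[I_LPL]; each hydrolysed TG
  releases 1 glycerol + 3 NEFA at the endothelium.
- **Spill-over**  f = (D_spill/100)·I_B/[I_art], clamped to [0, 1]
  (I_B = basal insulin): spill falls as insulin peaks and rises late
  postprandially.  Exact mass balance: spill + adipose influx = 3·TG
  hydrolysis.
- **Glucose uptake**  GLUT1·[G_art] + GLUT4·[G_art]·[I_AT]; a fraction
  `frac_use` is routed through G-6-P to glycerol-3-phosphate (two trioses
  per glucose) with a two-compartment delay τ_G3P.
- **ATL lipolysis** of stored TG: B_ATL + ATL_max/(1 + [I_AT]/K_ATL),
  insulin-inhibited.
- **Exchange**  concentration-gradient diffusion of glycerol (p_GLY) and
  NEFA (p_NEFA) between plasma (augmented by the LPL release) and the
  adipose compartment.
- **Re-esterification**  K_reester·[I_AT]·[NEFA_AT]·[G-3-P_AT], consuming
  3 NEFA + 1 G-3-P per TG resynthesised.

Fitting minimises C(p) = Σ_series Σ_i ((M(p,tᵢ) − μᵢ)/σᵢ)² over the five
measured series (TG, spill fraction, glucose, glycerol, NEFA), where μ, σ
are cohort means and cross-subject SDs at the seven sampling times.

## Worked example

```python
import numpy as np
from adipoflux import (
    CohortSpec, generate_cohort_fluxes, cohort_mean_forcing,
    simulate, decompose, peak_time, fasting_rate, homa_ir, adipo_ir, auc,
)

spec = CohortSpec(seed=1)                       # 16 synthetic subjects
table, dataset, truth = generate_cohort_fluxes(spec)
forcing = cohort_mean_forcing(table)

sim = simulate(truth, forcing)                  # dense 1-min trajectory
dec = decompose(sim)

print("fasting ATL lipolysis  :",
      round(fasting_rate(sim.t, sim.rates["atl_lipolysis"]), 3))
print("LPL-rate peak time     :",
      peak_time(dec.t, dec.rates["lpl_hydrolysis"]), "min")
print("arterial insulin peak  :",
      peak_time(sim.t, forcing("insulin", sim.t)), "min")
print("HOMA-IR (cohort mean)  :",
      round(homa_ir(forcing.fasting["glucose"], forcing.basal_insulin), 2))
print("measured TG flux (mean over 16 subjects):",
      np.round(dataset.mu["tg"], 3))
```

prints

```
fasting ATL lipolysis  : 0.243
LPL-rate peak time     : 300.0 min
arterial insulin peak  : 60.0 min
HOMA-IR (cohort mean)  : 1.62
measured TG flux (mean over 16 subjects): [0.091 0.079 0.095 0.132 0.202 0.26  0.274]
```

The fasting ATL rate (0.243 µmol/100 ml/min) is the basal +
insulin-inhibited lipolysis evaluated at basal insulin; the LPL hydrolysis
rate peaks long after arterial insulin (here pinned at the end of the
sampling window) because the 157-min LPL delay chain damps and lags the
insulin signal; the TG flux series rises across the meal accordingly.
Fitting this cohort back recovers the generating parameters — see
`fit_global` and the test suite.

A thin CLI wraps the same functions:

```bash
adipoflux synth --seed 1 --out cohort/
adipoflux fit --data cohort/study_table.csv --seed 1 --out fit
adipoflux select-terms --data cohort/study_table.csv --series spill --out rank.csv
```

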