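# Methods

## Model structure and assumptions

The model is a two-compartment description of metabolite exchange between
blood plasma and a lumped interstitial adipose space during a mixed-meal
challenge.  Its central assumptions:

- **Arterial concentrations are exogenous forcings.**  Insulin, glucose,
  TG, glycerol and NEFA time courses are measured inputs, not states; the
  model closes over the adipose depot only.  Sampled values are
  interpolated piecewise-linearly and extrapolated as constants outside
  the sampled range (a package convention — with seven samples, splines
  overshoot and can turn negative).
- **Insulin acts with delays.**  Enzyme transcription, secretion and
  transporter translocation are lumped into two linear three-compartment
  delay chains, a slow one gating LPL lipolysis (τ_LPL, ~157 min at the
  default truth) and a faster one gating everything inside the adipose
  compartment (τ_AT, ~21 min).  The chain output for a step input is the
  Erlang(3) cumulative response — this closed form is the analytic oracle
  used in the tests.
- **Stoichiometry is exact.**  1 TG → 1 glycerol + 3 NEFA at the LPL
  node; the spill fraction f = (D_spill/100)·I_B/[I_art] (clamped to
  [0, 1]) splits the 3 NEFA between plasma and tissue with machine-exact
  mass balance.  Stored-TG (ATL) lipolysis and re-esterification use the
  same 3:1 stoichiometry.
- **Sign convention.**  All measured fluxes are (arterial − venous) ×
  ATBF: uptake positive, release negative.  The printed rate laws of this
  model family are not mutually consistent in sign (the glucose-uptake
  law is written negative while glucose is taken up; the glycerol/NEFA
  laws are written release-positive), so the package fixes the one
  convention above and maps every term onto it explicitly
  (`config.SIGN_TABLE`).
- **Glycerol sink.**  The printed glycerol balance admits no sustained
  net glycerol uptake: in quasi-steady state the diffusion term tracks
  −ATL, so the net glycerol flux is −(ATL + LPL release) < 0.  An
  optional first-order sink (−k_sink·[GLY_AT], disabled by default) is
  provided for exploring the uptake regime; its functional form is a
  placeholder.
- **Initial conditions.**  Integration starts at −30 min from the fasting
  fixed point of the system with forcings frozen at fasting levels,
  solved algebraically (delay chains at I_B; GLY_AT, NEFA_AT, G-6-P,
  G-3-P pools from the steady-state balances).  A fixed point with
  non-negative states does not always exist: fasting re-esterification
  demand (2·frac_use·glucose uptake) must not exceed fasting lipolytic
  NEFA supply.  Infeasible parameter sets raise a diagnostic error; during
  optimisation they are penalised proportionally to the constraint
  violation so bounded least-squares can climb back into the feasible
  region.

## Parameters, units, defaults

Internal units: time min; insulin µU/ml (1 µU/ml = 6.0 pmol/l, converted
only at the I/O boundary); metabolites mmol/l; ATBF ml/(100 ml
tissue·min); fluxes µmol/(100 ml tissue·min).  With these choices a
concentration difference times ATBF is already in flux units and no scale
factors appear in the rate laws.  The adipose-compartment volume factor is
absorbed into the rate constants.

The 14 estimable parameters and their default (synthetic-truth) values:

| parameter | meaning | default | provenance |
|---|---|---|---|
| K_ad | LPL rate constant (per µU/ml per min) | 0.0096 | published baseline estimate |
| τ_LPL | LPL insulin delay (min) | 156.92 | published baseline estimate |
| τ_AT | adipose insulin delay (min) | 21.19 | published baseline estimate |
| P_GLY | glycerol exchange rate (min⁻¹) | 0.249 | published baseline estimate |
| P_NEFA | NEFA exchange rate (min⁻¹) | 0.0444 | published baseline estimate |
| D_spill | spill-over constant (% scale) | 30 | placeholder: basal spill ≈ 30%, near the classic constant-25% reference |
| GLUT1 | insulin-independent glucose uptake | 0.02 | placeholder |
| GLUT4 | insulin-dependent glucose uptake | 0.004 | placeholder |
| B_ATL | basal ATL lipolysis | 0.05 | placeholder |
| ATL_max | insulin-suppressible ATL lipolysis | 0.35 | placeholder |
| K_ATL | ATL half-inhibition insulin (µU/ml) | 10 | placeholder |
| K_reester | re-esterification constant | 0.001 | placeholder |
| frac_use | glucose fraction routed to G-3-P | 0.4 | placeholder |
| τ_G3P | G-3-P production delay (min) | 30 | placeholder |

The placeholders were chosen once for physiological plausibility, not
fitted to anything: together with basal insulin 8 µU/ml they give a
fasting ATL rate of 0.244 µmol/100 ml/min (reported human values are
~0.2–0.4), a fasting NEFA efflux of ~0.4 µmol/100 ml/min, fasting
re-esterification below fasting lipolysis (so the fasting fixed point
exists), and a re-esterification relaxation time of ~15 min (K_reester
values much larger make that relaxation unphysiologically fast, and
incidentally stiffen the ODE).  All parameters are bounded below by zero;
frac_use is additionally bounded above by one; the default search box is
[0, 10 × default] per parameter.

Solver: adaptive LSODA, rtol 1e−8 / atol 1e−10, dense output; the meal at
t = 0 is implicit in the forcing data.  A numba-compiled right-hand side
is used when all five forcings share one sample grid; it is bitwise
identical to the pure-Python reference implementation (asserted in
development) and roughly 4× faster.

## Estimation

The cost is C(p) = Σ_series Σ_i ((M(p,tᵢ) − μᵢ)/σᵢ)², with σ the
cross-subject standard deviation (SEM appears only in plots).  Points
with zero or undefined dispersion are excluded with a warning — notably
the two fasting spill-over points, where no meal tracer exists yet.

`fit_local` is bound-constrained trust-region least squares on the
weighted residual vector.  It uses central (3-point) difference
Jacobians: forward differences stall on the integration-error floor and
leave the joint fit several orders of magnitude above the optimum.

`fit_global` combines three stages, all reproducible from one seed:

1. a Price-style Controlled Random Search over the bound box (population
   max(10·dim, 250), reflection moves, default budget 4000 evaluations
   with a 1000-evaluation stall rule), whose best points are polished
   locally;
2. a divide-and-conquer refinement that fits each flux series in sequence
   over the parameters that act on it (TG: K_ad, τ_LPL; spill: D_spill;
   glucose: GLUT1, GLUT4, τ_AT; glycerol: P_GLY, B_ATL, ATL_max, K_ATL;
   NEFA: P_NEFA, K_reester, frac_use, τ_G3P), each stage seeded by
   pre-screened uniform + log-uniform multistarts, iterated twice;
3. a joint local polish of the best candidate.

The staged refinement mirrors the term-by-term workflow this model family
was built with, and is what makes the 14-dimensional problem tractable:
on a noiseless cohort it reaches cost ~1e−19 in ~2.5 min, where CRS +
polish alone lands in local optima around cost 0.3.

95% confidence intervals use the linearised covariance s²(JᵀJ)⁻¹ with the
normal 1.96 quantile (the source procedure does not state its quantile);
they may extend below zero because the linearisation ignores the bounds.
Singular JᵀJ falls back to the pseudo-inverse with a warning, and a
numerically zero sensitivity column yields an infinite interval.

## Identifiability and model selection

Profile likelihood: each parameter is fixed on a log-spaced grid (default
5 points per side spanning two decades, clipped to the bounds) and the
remaining 13 are re-fitted, warm-started from the neighbouring grid
point.  Refits use forward differences, looser tolerances (ftol 1e−6),
an iteration cap and rtol 1e−6 integration — the profile is compared
against a threshold of 3.84 (χ², 1 dof, 95%), so ~1e−2 cost accuracy
suffices.  Crossing the threshold on both sides within the grid ⇒
identifiable; one side ⇒ practically bounded (above/below); neither ⇒
practically non-identifiable.  The full 14-parameter scan takes ~2 min.

AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) ranks competing rate laws per
flux series, with n the number of usable points of that series (7, or 5
for the tracer-limited spill series) and RSS the weighted cost.  Built-in
variants cover delayed/undelayed/Michaelis–Menten LPL terms and
insulin-only/basal+insulin/constant spill terms.

## Synthetic cohort generator

The generator emulates the A-V study design: 16 subjects, samples at −30,
0, 60, 120, 180, 240, 300 min, fasting plateau then postprandial
excursions, constant ATBF of 3.0 ml/100 ml/min.  Arterial curves are a
fasting level plus a log-normal-shaped bump (insulin peaks at ~75 min
rising ~6-fold, glucose at ~60 min, TG late at ~210 min, glycerol roughly
doubles by ~120 min); NEFA is plateau − insulin-driven dip + late rebound
above fasting.  Between-subject variability is log-normal (CV 0.20 on
levels/amplitudes, 0.10 on peak times).  Per subject, the model is
simulated at the true parameters under that subject's forcing; flux noise
is additive Gaussian with SD 15% of each series' dynamic range (2%
proportional floor), and venous concentrations are back-computed as
arterial − flux/ATBF so the A-V calculation inverts the construction
exactly.  Tracer series: labelled TG hydrolysis is the LPL rate times a
log-normal meal-appearance envelope (peak ~150 min); labelled NEFA efflux
is the spill fraction times labelled hydrolysis, with spill noise
inflated 2.5× after 180 min to emulate label recycling.  Zero-dispersion
datasets (zero noise, or a single subject) receive a nominal positive
fitting weight equal to 15% of each series' dynamic range.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: structural model error (the data-generating
process is the fitted model itself), correlated measurement error (ATBF
error multiplies all four A-V fluxes of a subject), assay-specific noise
shapes, within-subject autocorrelation, demographics and diet-arm
structure.  One measurable consequence: on synthetic cohorts *more*
parameters are practically identifiable than on the human data this
design imitates — the default-cohort profile scan classifies 8 of 14
parameters identifiable (the glucose-routing and ATL-curve parameters are
pinned by the self-consistent steady-state identities), whereas on the
clinical data only 6 were, and the upper profiles of the exchange rates
P_GLY/P_NEFA are flat here because their high-rate limit is quasi-steady
at the 60-min sampling spacing.  The re-esterification constant is
practically non-identifiable in both settings (compensated by the adipose
G-3-P level), and the LPL, delay and spill parameters are identifiable in
both.

## Numerical conventions and degenerate inputs

- τ = 0 delay chains are rejected; undelayed variants use an explicit
  bypass flag (chain output ≡ arterial insulin), never division by zero.
- Spill fraction is clamped to [0, 1] (the raw law diverges as
  [I_art] → 0); zero arterial insulin is an error.
- AICc requires n − k − 1 > 0; zero hydrolysis makes the tracer spill
  fraction undefined (NaN, excluded); AUC requires ≥ 2 strictly
  increasing times.
- Peak times break ties to the earliest grid point; response slopes are
  ordinary least-squares magnitudes over the onset window [0, 120] min;
  fasting rates are means over [−30, 0].
- Decomposition closure (constituents sum to net fluxes; LPL-node mass
  balance) is enforced to 1e−9 on every simulation.

## Known limitations

- Chylomicron and VLDL triglyceride are lumped into one pool, as the
  single-tracer design cannot separate them.
- The cohort is fitted as a mean curve; there is no hierarchical
  per-subject model.
- The Jacobian CIs are symmetric linearisations; for parameters near a
  bound or with curved profiles the profile-likelihood intervals are the
  more faithful summary.
- The exact identifiability partition of the 14 parameters depends on the
  information content of the data; the synthetic default is documented
  above and not equivalent to clinical data.
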