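# Methods

This document records the models implemented in `cypddi`, the parameter
values shipped in `cypddi.presets` with their rationale, the synthetic-data
generators, and the numerical choices.  Units are stated everywhere;
concentrations are µM inside the solver and ng/mL at the reporting surface.

## 1. Reversible inhibition (`cypddi.ri`)

Velocities follow competitive Michaelis–Menten kinetics

```
v = Vmax · S / ( Km · (1 + I/Ki) + S )
```

- `fit_michaelis_menten` fits (Vmax, Km) to the I = 0 rows and flags
  non-identifiable designs: all substrate levels far above Km
  ("saturated") or far below ("first_order").
- `detect_inhibition` is a pre-fit screen: a one-sided test (α = 0.05) that
  the mean velocity at the top inhibitor level is reduced by at least 20 %
  relative to control.  With single replicates it falls back to a plain
  20 % threshold and flags the result as heuristic.  If no inhibition is
  detected, `fit_competitive_ki` returns the MM parameters with mode
  `NONE` instead of forcing a meaningless Ki.
- `fit_competitive_ki` is the canonical estimator: a global nonlinear
  least-squares fit of (Vmax, Km, Ki) over the whole S × I grid
  (`scipy.optimize.curve_fit`, xtol = ftol = 1e-14 so the noiseless case is
  recovered to machine precision).
- `dixon_regression` is the graphical cross-check: per-substrate OLS lines
  of 1/v on I; for a competitive inhibitor all lines intersect at
  I = −Ki.  The estimate is the median of −I* over all non-parallel line
  pairs; pairs whose slopes differ by less than a relative tolerance of
  1e-6 are excluded, and an all-parallel set raises `FitError`.

## 2. Time-dependent inhibition (`cypddi.tdi`)

Mechanism-based inactivation follows

```
kobs(I) = kinact · I / (KI + I)
```

- `estimate_kobs`: for each inhibitor level, OLS of ln(% remaining
  activity) on preincubation time; kobs = −slope.  Small negative slopes
  (noise at I = 0) are clamped to zero and flagged.  Activities may be
  normalised against matched-time controls ("corrected") or against t = 0.
- `fit_inactivation`: canonical estimate from the double-reciprocal plot
  `1/kobs = (KI/kinact)·(1/I) + 1/kinact`, so `kinact = 1/intercept` and
  `KI = slope/intercept`; a direct nonlinear fit of the hyperbola is
  reported alongside as a cross-check.  If the reciprocal intercept is not
  positive (no saturation information), the fit raises `FitError` rather
  than returning a divergent kinact.  Under 5 % assay noise this happens in
  roughly 2–3 % of replicates at the shipped designs; Monte-Carlo summaries
  therefore report medians over converged fits and state the converged
  count `n`.
- `efficiency(kinact, KI) = 1000 · kinact / KI` in mL/min/µmol (kinact in
  1/min, KI in µM).

Designs bind the assay to its target: a CYP3A5 design requires the
`*1/*3` microsome pool plus a CYP3A4-selective chemical knockout
(CYP3cide > 0), a CYP3A4 design requires the `*3/*3` pool with no
CYP3cide; violations raise `DesignError` at construction.

## 3. PBPK engine (`cypddi.pbpk`)

### Structure

Six drug compartments — gut lumen (amount), enterocyte, liver, central
blood, adipose, rest-of-body — plus four enzyme-state variables
(liver/gut × CYP3A4/CYP3A5, relative activity E ∈ [0, 1]).

- Absorption: first-order `ka` from the lumen into the enterocyte; only the
  fraction `Fa` of each dose enters the lumen.
- Gut extraction is **first-pass only**: the enterocyte receives absorbed
  drug and drains into the liver with the villous blood flow `Q_v`, which
  competes with gut metabolism (`Fg = Q_v / (Q_v + fu_gut·CLint_gut)` in
  the linear limit).  Systemic drug does not re-enter the enterocyte; this
  keeps gut CYP3A a bioavailability term, not a systemic clearance, which
  is the standard reduced-model treatment and was required to reproduce
  sensible oral exposures.
- Liver: well-stirred, inflow `Q_h·C_blood + Q_v·C_enterocyte`, elimination
  `fu_blood · CLint_u · C_liver/KpB_liver` plus optional renal clearance
  from blood.
- Adipose and rest: flow-limited, partition via blood-normalised
  `KpB = Kp / (blood:plasma)`.

### Intrinsic clearance scaling

Per-isoform microsomal clearance `Σ Vmax/Km,u` (µL/min/pmol, optionally
Michaelis–Menten saturable via `nonlinear_elimination`) is scaled by

- liver: `ISEF × abundance (pmol/mg) × MPPGL (40 mg/g) × liver mass (g)`,
- gut: `ISEF × total gut isoform (nmol) × 1000`,

then `× 60 / 1e6` to L/h.  `fm` shares per isoform fall out of the same
sum and feed the static oracle.

### Inhibition

With unbound perpetrator concentration `Iu` at the enzyme site:

- reversible: each isoform's CLint is scaled by `1 / (1 + Iu/Ki)`;
- mechanism-based: `dE/dt = kdeg·(1 − E) − 60·kinact · Iu/(KI + Iu) · E`
  (kinact converted 1/min → 1/h), with `kdeg = 0.0193 h⁻¹` (liver) and
  `0.03 h⁻¹` (gut) — standard CYP3A turnover values.

The perpetrator is simulated first on its own disposition model; a dense
piecewise interpolant of its unbound liver and enterocyte concentrations
then forces the victim ODE.  A `constant_perpetrator_unbound` clamp mode
replaces the interpolant with fixed `Iu` values, which is what makes the
dynamic model directly comparable to the mechanistic-static oracle

```
AUCR = 1 / ( Σ_i fm_i / (RI_i · TDI_i) + 1 − Σ_i fm_i ),
TDI_i = 1 + 60·kinact·Iu / ( kdeg · (KI + Iu) ).
```

A test verifies dynamic-vs-static agreement within 5 % in a liver-only,
low-extraction configuration.

### Populations

Abundance presets (pmol/mg liver; nmol total gut):

| population | liver 3A4 | liver 3A5 | gut 3A4 | gut 3A5 |
|---|---|---|---|---|
| Chinese expresser (`*1/*3`) | 120 | 82 | 58 | 21.5 |
| Chinese non-expresser (`*3/*3`) | 120 | 0 | 58 | 0 |
| Caucasian expresser | 137 | 103 | 66.2 | 24.6 |

Physiology (Chinese adult): liver 1500 g, hepatic blood flow 80 L/h,
villous flow 16 L/h, adipose 11 kg (perfusion 13 L/h), body 61 kg, rest
perfusion 210 L/h.  Caucasian values scale with the larger body size.

### Compound parameters

Victim (tacrolimus, MW 804.0): `fu_plasma = 0.013`, blood:plasma = 15
(extensive erythrocyte binding via FKBP-12 — both literature-typical),
`ka = 2 h⁻¹`, `Fa = 0.95`, Kp adipose 1000 / rest 1 (highly lipophilic),
no renal clearance, `ISEF = 0.24`, pathway kinetics from recombinant-enzyme
Vmax/Km per isoform.

Perpetrators carry the measured inhibition constants (STA: Ki 0.15 µM on
CYP3A4, 0.11 µM on CYP3A5, kinact/KI 0.11/2.45 on CYP3A4; SIA: Ki 8.74 µM
on CYP3A5 only, kinact/KI 0.019/2.54 on CYP3A4 and 0.014/2.07 on CYP3A5).
Their own disposition parameters (fu_plasma 0.10/0.08, B:P 0.8/0.9, ka
1.5/1.2 h⁻¹, Fa 0.85, hepatic CLint,u 300/200 L/h) are **illustrative**
round values chosen once for plausible lignan-like exposure; they set the
magnitude of the driving `Iu(t)` and are the main tuning surface of the DDI
predictions.

Doses: victim 2 mg; STA 7.325 mg and SIA 7.20 mg (equimolar content of the
herbal preparation).  Multidose scenario: perpetrator BID for 13 days, with
the victim dose co-administered at t = 288 h (first dose of day 13) and
metrics computed on the window from that time.

## 4. Exposure metrics (`cypddi.metrics`)

- AUC by trapezoid on the output grid; `mode="infinity"` adds
  `C_last/λz`, where λz is fitted log-linearly over the last third of
  post-Tmax points (minimum 5 points); `mode="last"` skips extrapolation.
- `fold_error(pred, obs) = max(p/o, o/p)` (symmetric, ≥ 1);
  `aucr = AUC_with / AUC_alone`.
- Printed-value verification uses banker's rounding
  (`round_half_even`, Decimal ROUND_HALF_EVEN, 2 d.p.), the convention
  under which the reference tables are self-consistent; cells that fail it
  by any rounding rule are flagged, not reproduced.

## 5. Synthetic generators (`cypddi.synth`)

All generators require an explicit seed and are exact at `cv = 0` (tested
to 1e-12).  Noise is multiplicative log-normal `exp(N(0, cv²))`, which
keeps velocities/activities positive and matches the roughly constant CV of
plate-reader assays.  `gen_observed_profiles` perturbs ISEF, ka and adipose
Kp across subjects and adds residual noise, returning tidy per-subject
profiles with mean/p5/p95 summaries.  Scope: the generators model only the
structures the estimators assume (competitive RI, hyperbolic TDI, this PBPK
model) — they exist to validate recovery, not to emulate every assay
artefact.

## 6. Numerical choices

- ODEs: `scipy.solve_ivp` LSODA, `rtol = 1e-7`, `atol = 1e-9`, solved
  piecewise between dose times with lumen boluses, dense output evaluated
  on a 0.05 h grid; washout defaults to 400 h so extrapolated AUC terms are
  small.  A tolerance-refinement test confirms results are converged.
- Negative states beyond tolerance raise `SolverError`; tiny negative
  values are clipped.
- Fits: `curve_fit` with tight tolerances (see above);
  `scipy.stats.linregress` for all OLS lines.
- Monte-Carlo protocols use 200 replicates per setting with deterministic
  sub-seeds below 2³¹ derived from the user seed.

## 7. Limitations

- Reduced compartment set: no kidney/brain/muscle split; renal clearance is
  a single linear term from blood.
- Perpetrator PK is one-way: the victim does not inhibit the perpetrator,
  and perpetrators do not interact with each other.
- Perpetrator disposition parameters are illustrative (see above), so
  absolute AUCRs inherit their uncertainty; mechanism orderings and
  genotype contrasts are the robust outputs.
- The enterocyte is a single well-stirred segment; regional gut physiology
  and transporters (P-gp) are not modelled, although tacrolimus is a P-gp
  substrate.
- The double-reciprocal TDI estimator loses a small fraction of noisy
  replicates to non-positive intercepts; these are excluded, which slightly
  biases the reported medians toward saturating datasets.
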