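# cypddi

In-vitro CYP3A inhibition kinetics and a genotype-stratified PBPK
drug–drug-interaction (DDI) model for tacrolimus with the Schisandra lignans
schisantherin A (STA) and schisandrin A (SIA).

The package covers the whole chain from raw microsomal assay tables to
simulated clinical exposure ratios:

1. **Reversible inhibition** (`cypddi.ri`) — Michaelis–Menten and global
   competitive-inhibition fits (`fit_competitive_ki`), a statistical
   inhibition screen (`detect_inhibition`), and Dixon-plot regression as a
   graphical cross-check.
2. **Time-dependent inhibition** (`cypddi.tdi`) — per-concentration
   inactivation rates `kobs` from log-linear activity decay
   (`estimate_kobs`), `(kinact, KI)` from the double-reciprocal plot with a
   nonlinear cross-check (`fit_inactivation`), and the inactivation
   efficiency `1000 * kinact / KI` in mL/min/µmol.
3. **PBPK engine** (`cypddi.pbpk`) — a reduced whole-body model (gut lumen,
   enterocyte, liver, central blood, adipose, rest) with CYP3A4/CYP3A5
   abundance-scaled intrinsic clearance, first-pass gut extraction,
   reversible inhibition via `1/(1 + Iu/Ki)` and mechanism-based enzyme
   turnover `dE/dt = kdeg(1−E) − kinact·Iu/(KI+Iu)·E` in liver and gut.
4. **DDI pipeline** (`cypddi.pipeline`) — genotype baselines, the full
   scenario grid (2 genotypes × 2 perpetrators × single/multidose ×
   RI/TDI/combined), exposure metrics, fold-error verification and report
   rendering.
5. **Synthetic data** (`cypddi.synth`) — seeded generators for RI assays,
   TDI time-courses and noisy observed profiles, exact at zero noise.

CYP3A5 genotype matters because tacrolimus is cleared by both CYP3A4 and
CYP3A5: `CYP3A5*1/*3` expressers carry an extra clearance pathway that is
barely inhibited by SIA, so the predicted interaction differs sharply
between genotypes.

## Worked example

Fitting a competitive Ki from a synthetic assay at the study design
(`examples/01_fit_reversible_inhibition.py`):

```text
Nonlinear competitive fit: Ki = 0.1537 uM (Vmax = 9.893, Km = 0.390, R^2 = 0.9942)
Dixon-plot cross-check:    Ki = 0.1552 uM from 6 line intersections
```

Genotype baselines for a 2 mg tacrolimus dose
(`examples/03_genotype_baselines.py`):

```text
expresser       AUC =   45.40 ng/mL*h  Cmax =  14.38 ng/mL  Tmax = 0.45 h  (reference AUC 60.83, fold error 1.34)
non_expresser   AUC =  170.00 ng/mL*h  Cmax =  26.57 ng/mL  Tmax = 0.50 h  (reference AUC 119.02, fold error 1.43)
```

The full DDI grid (`examples/04_ddi_scenario_grid.py`) produces one AUC
ratio per (population, perpetrator, regimen, mechanism) cell, e.g. for STA
in expressers: RI-only 2.84, TDI-only 1.26 (single dose) rising to 1.68
after 13 days of BID dosing, combined 3.24 → 3.88.  SIA, which barely
inhibits CYP3A4 reversibly, shows a near-unity RI-only ratio (1.03) but a
clear multidose TDI effect (1.69).

There is also a thin CLI mirroring the library:

```bash
cypddi synth ri --params params.yaml --seed 1 --out assay.csv
cypddi fit-ri assay.csv
cypddi ddi --out ddi_report
```

## Repository layout

- `src/cypddi/` — the library (datasets, ri, tdi, pbpk, metrics, presets,
  synth, pipeline, cli).
- `examples/` — five short narrative scripts, one per capability; each
  prints real numbers with a line of interpretation.
- `tests/` — unit, property-based and end-to-end tests, including
  `tests/test_acceptance.py`.
- `docs/methods.md` — model equations, parameter choices with rationale,
  numerical settings and limitations.
- `scripts/acceptance.py` — end-to-end reproduction entry point.

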