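"""Fit kinact / KI from a synthetic time-dependent inhibition assay.

Generates a preincubation time-course for schisantherin A (STA) on CYP3A4,
estimates kobs at each inhibitor level from the log-linear activity decay,
then recovers (kinact, KI) from the double-reciprocal plot and reports the
inactivation efficiency in mL/min/umol.
"""

from cypddi import efficiency, estimate_kobs, fit_inactivation, presets
from cypddi.synth import TDISynthSpec, gen_tdi_dataset

design = presets.tdi_design("STA", "CYP3A4")
spec = TDISynthSpec(design=design, kinact=0.11, ki_half=2.45, cv=0.0, seed=7)
dataset = gen_tdi_dataset(spec)

kobs = estimate_kobs(dataset)
for conc, k in sorted(kobs.kobs_map.items()):
    print(f"  kobs([I] = {conc:5.2f} uM) = {k + 0.0:.5f} 1/min")

fit = fit_inactivation(kobs)
print(f"\nDouble-reciprocal fit: kinact = {fit.kinact:.4f} 1/min, "
      f"KI = {fit.ki_half:.4f} uM")
print(f"Inactivation efficiency = {efficiency(fit.kinact, fit.ki_half):.2f} "
      "mL/min/umol")

print("\nAt zero assay noise the estimator returns the generating values "
      "exactly (kinact = 0.11, KI = 2.45), giving an efficiency of 44.90 "
      "mL/min/umol.")
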