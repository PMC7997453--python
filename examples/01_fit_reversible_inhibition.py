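"""Fit a competitive Ki from a synthetic reversible-inhibition assay.

Generates a CYP3A4 velocity grid for schisantherin A (STA) at the preset
substrate/inhibitor concentrations, runs the inhibition screen plus the
global competitive fit, and cross-checks with a Dixon-plot regression.
"""

from cypddi import dixon_regression, fit_competitive_ki, presets
from cypddi.synth import RISynthSpec, gen_ri_dataset

design = presets.ri_design("STA", "CYP3A4")
spec = RISynthSpec(design=design, vmax=10.0, km=0.4, ki=0.15, cv=0.05, seed=42)
dataset = gen_ri_dataset(spec)

fit = fit_competitive_ki(dataset)
print(f"Nonlinear competitive fit: Ki = {fit.ki:.4f} uM "
      f"(Vmax = {fit.vmax:.3f}, Km = {fit.km:.3f}, R^2 = {fit.r_squared:.4f})")

dixon = dixon_regression(dataset)
print(f"Dixon-plot cross-check:    Ki = {dixon.ki:.4f} uM "
      f"from {len(dixon.intersections)} line intersections")

print("\nWith 5% assay noise both estimators land near the true Ki of "
      "0.15 uM; the Dixon value is a graphical diagnostic, the nonlinear "
      "fit is the reported number.")
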