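"""Binding stoichiometry from a Soret-band titration.

Two synthetic titrations: a double-histidine peptide saturating at
hemin:peptide ~0.9 and a histidine-free control with no kink. The
two-segment fit locates the saturation ratio; AIC model selection
separates specific from nonspecific binding.
"""

from hemesam.synth import gen_titration
from hemesam.titration import classify_binding, fit_breakpoint

double_his = gen_titration(breakpoint=0.9, slope_low=1.0, slope_high=0.2,
                           noise_sd=0.01, n=12, seed=2)
no_his = gen_titration(breakpoint=0.9, slope_low=0.7, slope_high=0.7,
                       noise_sd=0.01, n=12, seed=3)

for name, series in (("double-histidine", double_his),
                     ("no-histidine control", no_his)):
    fit = fit_breakpoint(series, n_boot=1000, seed=7)
    cls = classify_binding(fit)
    print(f"{name}:")
    print(f"  breakpoint {fit.breakpoint:.3f} "
          f"(95% CI {fit.breakpoint_ci[0]:.3f}-{fit.breakpoint_ci[1]:.3f}), "
          f"slopes {fit.slope_low:.2f} -> {fit.slope_high:.2f}")
    print(f"  classification: {cls}")
print("\nA saturation ratio near 0.9 means two hemes bind per "
      "two-histidine chain at full coordination; the control's linear "
      "absorbance marks nonspecific association only.")
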