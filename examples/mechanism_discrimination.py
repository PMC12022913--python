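"""Which transport mechanism generated a junction dataset?

Simulates a 70-scan ensemble from the hopping reference model with
0.1-decade scan dispersion, summarizes it to a median curve, fits both
single-level models and compares them by AIC.
"""

from hemesam.jv import compare_models, fit_model, summarize_traces
from hemesam.synth import (DEFAULT_PACKING_PER_CM2, gen_jv_ensemble,
                           reference_hopping_params)

traces = gen_jv_ensemble(reference_hopping_params(), noise_decades=0.1,
                         n_scans=70, seed=1)
summary = summarize_traces(traces)

fit_h = fit_model(summary, "hopping", DEFAULT_PACKING_PER_CM2)
fit_t = fit_model(summary, "tunneling", DEFAULT_PACKING_PER_CM2)
sel = compare_models(fit_h, fit_t)

print(f"hopping fit:   RMSE {fit_h.residual_norm:.4f} decades, "
      f"AIC {fit_h.aic:.1f}")
print(f"  level offset {fit_h.params.level_offset:.3f} eV, "
      f"lambda {fit_h.params.lambda_reorg:.3f} eV, "
      f"gamma_l {fit_h.params.gamma_l:.2e} eV")
print(f"tunneling fit: RMSE {fit_t.residual_norm:.4f} decades, "
      f"AIC {fit_t.aic:.1f}")
print(f"preferred mechanism: {sel.preferred} (delta AIC {sel.delta_aic:.1f})")
print("\nThe fitted level offset and reorganization energy recover the "
      "generating values (0.15 / 0.30 eV); the tunneling model cannot "
      "reproduce the thermally broadened rise and loses by AIC.")
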