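"""Single-level transport models: hopping vs tunneling I-V shapes.

Evaluates both mechanisms for a level at comparable energetics and
prints current densities across the sweep. The hopping current is
thermally activated (Marcus electrode kinetics); the tunneling current
is a Lorentzian-resonance Landauer integral.
"""

import numpy as np

from hemesam.synth import (DEFAULT_PACKING_PER_CM2, reference_hopping_params,
                           reference_tunneling_params)
from hemesam.transport import iv_curve

V = np.array([-1.0, -0.6, -0.2, 0.2, 0.6, 1.0])
hop = reference_hopping_params()
tun = reference_tunneling_params()

J_hop = iv_curve(hop, V, DEFAULT_PACKING_PER_CM2)
J_tun = iv_curve(tun, V, DEFAULT_PACKING_PER_CM2)

print(f"{'V (V)':>8} {'J hopping (A/cm2)':>20} {'J tunneling (A/cm2)':>20}")
for v, jh, jt in zip(V, J_hop, J_tun):
    print(f"{v:8.2f} {jh:20.3e} {jt:20.3e}")
print("\nAt low and moderate bias the hopping junction (level 0.15 eV, "
      "lambda 0.3 eV) passes more current than the off-resonant "
      "tunneling junction (level 0.4 eV), and its thermally broadened "
      "rise has a distinctly different shape from the sharp Lorentzian "
      "resonance the tunneling model shows near 0.8 V.")
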