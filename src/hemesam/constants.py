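"""Physical constants in the eV-based unit system used throughout.

Energies are carried in eV internally; currents are converted to SI
amperes only at the model boundary (per-molecule current, areal current
density). CODATA 2018 exact values.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    q: float = 1.602176634e-19       # elementary charge, C
    h_planck: float = 4.135667696e-15  # Planck constant, eV s
    k_B: float = 8.617333262e-5      # Boltzmann constant, eV/K

    @property
    def hbar(self) -> float:
        """Reduced Planck constant, eV s."""
        return self.h_planck / (2.0 * 3.141592653589793)


CONSTANTS = PhysicalConstants()
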