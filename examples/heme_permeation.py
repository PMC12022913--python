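"""Coarse-grained heme infiltration into the four sequence analogs.

Runs the 1-D Langevin model (30 hemes, 3 replicas) for PHH, PAH, PHA
and PAA site layouts and reports terminal histidine-site occupancy,
binding onset, and nonspecific in-slab contacts.
"""

import numpy as np

from hemesam.permeation import (bound_fraction, config_for_sequence,
                                nonspecific_contacts, simulate_permeation)

print(f"{'seq':>4} {'sites':>12} {'occupancy':>10} {'t(half)':>9} "
      f"{'nonspecific':>12}")
for seq in ("PHH", "PAH", "PHA", "PAA"):
    cfg = config_for_sequence(seq, n_steps=100_000, n_replicas=3, seed=7)
    trajs = simulate_permeation(cfg)
    times, so, hb, _, _ = bound_fraction(trajs)
    _, ns, _ = nonspecific_contacts(trajs)
    term = float(np.mean(so[-max(len(so) // 10, 1):]))
    t_half = (float(times[np.argmax(so >= 0.5 * term)])
              if term > 0 else float("nan"))
    depths = ",".join(f"{d:.1f}" for d in cfg.his_depths) or "none"
    print(f"{seq:>4} {depths:>12} {term:10.2f} {t_half:9.2f} "
          f"{float(ns[-1]):12.1f}")

print("\nShallow sites (PHH, PAH at 2.5 nm) coordinate heme quickly; "
      "the buried site (PHA at 1.0 nm) binds late because the crowding "
      "barrier slows penetration; PAA has no histidine and only "
      "nonspecific in-slab contacts. Times are simulation units.")
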