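"""Current-density enhancement as a function of heme loading.

Generates J-V ensembles across heme:peptide ratios 0-8 whose median
current follows a saturating 1000-fold multiplier, then measures the
enhancement at -1 V and fits the saturating loading curve.
"""

from hemesam.jv import enhancement_ratio, loading_curve
from hemesam.synth import gen_loading_series

summaries = gen_loading_series(plateau_fold=1000.0,
                               half_saturation_ratio=1.0,
                               ratios=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                               noise_decades=0.1, n_scans=70, seed=11)

table, hill = loading_curve(summaries, V=-1.0)
print(table[["ratio", "median_logJ", "n_scans"]].to_string(index=False))

enh = enhancement_ratio(summaries[8.0], summaries[0.0], V=-1.0)
print(f"\nenhancement at ratio 8 vs 0: {enh.ratio:.0f}-fold "
      f"[{enh.ci_low:.0f}, {enh.ci_high:.0f}]")
print(f"fitted half-saturation ratio: {hill.half_saturation:.2f}, "
      f"plateau {hill.plateau_fold:.0f}-fold")
print("\nThe median current climbs three decades with loading and "
      "saturates: heme coordination, not packing changes, drives the "
      "conductance gain.")
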