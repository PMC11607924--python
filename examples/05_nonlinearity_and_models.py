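"""How saturation breaks linear calibration, and how the models compare.

Sweeps the saturation strength and tracks the preset PLS test error, then
runs the replicated preset-PLS vs preset-GBT comparison for the minor
analyte (GLM) in the severe regime.
"""

from scipy import stats

import mixcal

sweep = mixcal.saturation_sweep(analyte="ALG", seed=0)
print("PLS test RMSEP vs saturation strength (ALG):")
print(sweep.round(3).to_string(index=False))
rho = stats.spearmanr(sweep["saturation_k"], sweep["pls_rmsep"]).statistic
print(f"Spearman rho(saturation, PLS RMSEP) = {rho:.2f}")
print("-> the linear model degrades monotonically as spectra leave the")
print("   Beer–Lambert regime; the tree model's error is dominated by the")
print("   5-level design's interpolation floor and moves much less.\n")

table = mixcal.pls_gbt_ordering(analyte="GLM", n_replicates=10, base_seed=0)
wins = int(table["gbt_wins"].sum())
print("Severe regime (saturation_k=2, noise 0.005 AU), GLM, 10 replicates:")
print(table.round(3).to_string(index=False))
print(f"\nGBT beat PLS in {wins}/10 replicates "
      f"(mean RMSEP: GBT {table.gbt_rmsep.mean():.3f}, "
      f"PLS {table.pls_rmsep.mean():.3f} µg/mL).")
print("Under severe non-linearity the two approaches are close: boosted")
print("trees avoid the linear model's bias but pay an interpolation floor")
print("set by the 5-level calibration design.")
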