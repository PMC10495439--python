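"""Pool trial-level subgroup hazard ratios and compute per-cancer HRD.

Builds a small synthetic table of randomized-trial results (hazard ratio
plus 95% CI for ICI vs standard-of-care, separately in biomarker-positive
and biomarker-negative patients), pools each subgroup with a
DerSimonian-Laird random-effects model, and prints the hazard-ratio
difference HRD = HR(neg) - HR(pos) per cancer with its interaction p.
A positive HRD means biomarker-positive patients benefit more.
"""

from predscreen.meta import compute_predictiveness, predictiveness_correlation
from predscreen.simulate import paper_pattern_config, simulate_trial_table

cfg = paper_pattern_config(seed=1)
trials, truth = simulate_trial_table(cfg)
print(f"{len(trials)} trial records across {cfg.n_cancers} cancer types\n")

res_os = compute_predictiveness(trials, "OS")
res_pfs = compute_predictiveness(trials, "PFS")
cols = ["cancer", "hr_pos", "hr_neg", "hrd", "p_interaction", "i2_pos"]
print(res_os.table[cols].round(3).to_string(index=False))

rho, p = predictiveness_correlation(res_os, res_pfs)
print(f"\nOS-vs-PFS HRD Spearman rho = {rho:.2f} (p = {p:.3g})")
print("Planted OS HRDs ranged over", sorted(round(v, 2)
                                            for v in truth.hrd_os.values()))
print("Cancers whose recovered HRD tracks the plant indicate the pooling "
      "and interaction test are working.")
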