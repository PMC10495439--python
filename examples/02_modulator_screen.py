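"""Find transcriptomic modulators of biomarker predictiveness.

Step 1: correlate per-cancer median gene expression with the per-cancer
HRD (both endpoints) and keep genes significant for both.  Step 2: rank
the survivors by the Wald z of the treatment-arm Cox interaction
hazard ~ a*PD-L1 + b*V + d*PD-L1*V with both covariates median-split.
A positive d (and z) means high expression of V erodes the biomarker's
favorable association with outcome.
"""

from predscreen.meta import compute_predictiveness
from predscreen.screen import (cross_cancer_screen, median_profile,
                               rank_interactions)
from predscreen.simulate import (paper_pattern_config, simulate_cohort,
                                 simulate_expression_panel,
                                 simulate_trial_table)

cfg = paper_pattern_config(seed=2)
trials, _ = simulate_trial_table(cfg)
pred_os = compute_predictiveness(trials, "OS")
pred_pfs = compute_predictiveness(trials, "PFS")

panel, sample_cancer, _ = simulate_expression_panel(cfg)
medians = median_profile(panel, sample_cancer)
screened = cross_cancer_screen(medians, pred_os, pred_pfs)
n_pass = int(screened["passes"].sum())
print(f"screen: {n_pass}/{len(screened)} genes pass (p < 0.05 for OS and "
      f"PFS HRD)")
print(screened.head(3).round(3).to_string(index=False), "\n")

clinical, expression, _ = simulate_cohort(cfg)
ici_arm = clinical[clinical["arm"] == "ICI"]
candidates = screened.loc[screened["passes"], "gene"].tolist()
ranked = rank_interactions(ici_arm, expression, cfg.pdl1_gene, candidates)
print("interaction ranking (ICI arm, OS):")
print(ranked.head(5).round(3).to_string(index=False))
print(f"\nThe planted modulator is {cfg.planted_gene}; a top rank with "
      "positive z reproduces the intended benefit-eroding interaction.")
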