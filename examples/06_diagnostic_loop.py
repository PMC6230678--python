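"""The multi-loop diagnostic pipeline end to end.

Raw lane counts and clinical metadata go in; out come per-patient
decisions: the EoE probability gate (p(EoE) > 25, from the pluggable
multinomial model), the IGHE loop annotation (score > 37.5) when an IGHE
score column is present, and the FI loop (standardized FI-score vs its
ROC cutoff) on the EoE samples only — controls never receive an FI call.
"""

import numpy as np

import fiscope as fs

config = fs.SimulationConfig(seed=1)
raw, _ = fs.simulate_counts(config)
meta = fs.simulate_metadata(config)

# attach IGHE scores (here synthetic) so the IGHE loop has input
table = meta.table.copy()
table["ighe_score"] = np.random.default_rng(0).uniform(0, 80, len(table)).round(1)
meta = fs.ClinicalTable(table)

cfg = fs.PipelineConfig(use_eoe_gate=True, cutoff_policy="max-specificity", seed=0)
result = fs.run_pipeline(raw, meta, cfg)

print(result.decisions[["group", "p_EoE", "eoe_gate", "ighe_elevated",
                        "fi_score", "fi_call"]].round(2).head(12))
print(f"\nFI loop: AUC {result.roc.auc:.2f}, cutoff {result.scores.cutoff:.3f}, "
      f"specificity {result.roc.specificity:.2f}")
# Each loop is an independent annotation: the EoE gate screens who enters
# the FI loop, while the IGHE flag marks the local-allergy subpopulation.
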