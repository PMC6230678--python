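"""Generate a synthetic three-group cohort and inspect what was planted.

The generator emulates a targeted esophageal mRNA panel study: 18 healthy
controls, 13 EoE patients without food impaction and 14 with, a 74-gene
endogenous panel plus housekeeping/spike-in controls, negative-binomial
counts, a log-normal per-lane technical factor, and the impaction-specific
down-regulation of mast-cell/Th2/motility transcripts.
"""

import fiscope as fs

config = fs.SimulationConfig(seed=1)
raw, truth = fs.simulate_counts(config)
meta = fs.simulate_metadata(config)

print(f"lanes x probes: {raw.counts.shape}")
print(f"group sizes: {truth.labels.value_counts().to_dict()}")
print("planted impaction folds (EoE+FI vs EoE no FI):")
for gene, fold in truth.fold_maps["fi_vs_nofi"].items():
    print(f"  {gene:8s} x{fold}")
print("\nfirst metadata rows:")
print(meta.table[["group", "dysphagia", "asthma", "eos_max"]].head())
# Folds < 1 mean the transcript is planted lower in impaction patients;
# downstream stages must recover exactly these genes with negative weights.
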