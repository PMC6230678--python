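"""Cohort characteristics table with exact pairwise statistics.

Binary traits get n/N (%) per group and two-sided Fisher exact p-values per
group pair; numeric traits get median (range) and Kruskal-Wallis/Dunn p.
"""

import fiscope as fs

config = fs.SimulationConfig(seed=1)
meta = fs.simulate_metadata(config)
summary = fs.cohort_table(meta)

formatted = summary.format()
print(formatted[["EoE_FI", "EoE_no_FI", "Control", "p EoE_FI vs EoE_no_FI"]]
      .head(10).to_string())
# Simulated prevalences emulate a pediatric EoE cohort, so dysphagia is
# universal in the impaction group and the Fisher p against the
# non-impaction group is small.
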