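"""Per-indication length-of-treatment summary of included courses.

Median LOT and IQR per (indication, acquisition) plus post-discharge
therapy metrics: the share of courses with any post-discharge days and,
among those, the mean share of the LOT given after discharge.
"""

from abxlot import SimulationConfig, generate, run_pipeline, summarize

sim = generate(SimulationConfig(n_patients=1500, seed=7))
result = run_pipeline(sim.prescriptions, sim.admissions)
summary = summarize(result.included)

table = summary.table.sort_values("n", ascending=False).head(10)
print("ten most frequent indications (n, median LOT [Q1-Q3] in days):")
print(table.to_string(index=False))

print("\npost-discharge therapy:")
print(summary.post_discharge.to_string(index=False))
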