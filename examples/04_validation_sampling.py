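"""Draw the stratified manual-validation sample.

5% of UTI, RTI and intra-abdominal courses, 5% of the remaining
indications and 20% of extended courses (LOT > 45 days, drawn before the
>45 d exclusion applies) are selected for chart review, reproducibly
under a fixed seed.
"""

from collections import Counter

from abxlot import SamplingPlan, SimulationConfig, generate, run_pipeline
from abxlot.records import ExclusionReason
from abxlot.surveillance import assign_stratum, draw_validation_sample

sim = generate(SimulationConfig(n_patients=1500, seed=7))
result = run_pipeline(sim.prescriptions, sim.admissions)
eligible = [
    c
    for c in result.all_courses
    if c.exclusion_reason is None
    or c.exclusion_reason is ExclusionReason.duration_over_45d
]

plan = SamplingPlan(seed=11)
sample = draw_validation_sample(eligible, plan)
by_id = {c.course_id: c for c in eligible}

strata = Counter(assign_stratum(by_id[i], plan).value for i in sample)
sizes = Counter(assign_stratum(c, plan).value for c in eligible)
print(f"sampled {len(sample)} of {len(eligible)} eligible courses:")
for stratum, n in sorted(strata.items()):
    frac = plan.fractions[[s for s in plan.fractions if s.value == stratum][0]]
    print(f"  {stratum:10s} {n:4d} of {sizes[stratum]:4d}  (plan {frac:.0%})")
print("\nsame seed reproduces the identical sample; reviewers fill in verdicts per course.")
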