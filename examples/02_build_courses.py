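"""Run the full pipeline: raw tables -> treatment courses -> exclusion flow.

Prescriptions are filtered to therapeutic J01 agents, linked into courses
by the 24 h gap rule, classified CA/HA against admissions, and passed
through the exclusion cascade.  The flow table reproduces the selection
arithmetic: input = remaining + sum of exclusions.
"""

from abxlot import SimulationConfig, generate, run_pipeline

sim = generate(SimulationConfig(n_patients=300, seed=42))
result = run_pipeline(sim.prescriptions, sim.admissions)

print("pipeline stages (counts of records/courses surviving each step):")
for stage, n in result.stage_counts.items():
    print(f"  {stage:30s} {n}")

print("\nexclusion flow:")
print(result.flow.to_frame().to_string(index=False))

course = result.included[0]
print("\none included course:")
print(f"  course_id        {course.course_id}")
print(f"  final diagnosis  {course.definitive_indication.key()}")
print(f"  start/stop       {course.start_ts} -> {course.stop_ts}")
print(f"  LOT              {course.lot_days} calendar days"
      f" ({course.post_discharge_days} post-discharge)")
print(f"  acquisition      {course.acquisition}")
print(f"  drugs            {', '.join(course.drug_names)}")
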