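# Methods

## The surveillance model

`abxlot` operationalizes a simple observational model of in-hospital
antibiotic use: a patient's therapeutic antibiotic exposure is a sequence
of prescriptions, and an *infection episode* manifests as a maximal run of
prescriptions with no more than 24 hours between one prescription's stop
and the next one's start.  Everything downstream — indication, duration,
acquisition class — is derived from that segmentation:

- **Course** = connected component of the per-patient interval graph whose
  edges join prescriptions with a gap ≤ 24 h (the greedy sweep the
  implementation uses is provably equivalent and is property-tested
  against a brute-force connected-components oracle).
- **LOT** (length of treatment) = inclusive calendar-day span of the
  course, `(stop date − start date) + 1`, irrespective of how many agents
  or doses are given on each day.  Two overlapping agents on the same day
  count once.
- **Definitive indication** = the indication registered on the
  latest-starting labeled prescription of the course; the earliest one is
  kept as the "first" (working-diagnosis) indication.
- **Acquisition**: community-acquired (CA) if therapy started < 48 h after
  admission, hospital-acquired (HA) otherwise.
- **Post-discharge therapy** = course calendar days strictly after the
  discharge date; reported both as a count and as a percentage of LOT.

### Assumptions

- Prescription timestamps are trustworthy at minute resolution in a single
  implicit timezone; calendar dates are obtained by truncation.  Date-only
  source extracts would coarsen the 24 h and 48 h rules.
- The indication registration tool is mandatory, so unlabeled
  prescriptions are the exception; they are still assembled into courses
  and only flag the course when no member carries any label.
- Prescription data is the only signal: therapy administered elsewhere
  (transfers, OPAT, pre-admission treatment by a GP) is invisible, which
  is exactly what the manual-validation workflow is designed to quantify.

## Tunable parameters

| parameter | default | unit | role |
|---|---|---|---|
| `gap_hours` | 24 | h | max linkage gap between stop and next start; inclusive (exactly 24 h links) |
| `ca_ha_boundary_hours` | 48 | h | CA/HA boundary; exactly 48 h classifies HA (conservative nosocomial attribution) |
| `min_admission_hours` | 12 | h | below this an admission does not count as hospitalization |
| `max_course_days` | 45 | d | longer courses are excluded (dominated by never-stopped prescriptions) |
| `pediatric_age_years` | 18 | y | age cut for the pediatric exclusion |
| `long_term_threshold_days` | 28 | d | presumed-prophylaxis duration cut for the listed long-term agents |
| `cotrimoxazole_low_dose_mg` | 480 | mg/day | at or below: prophylactic beyond 14 d; above: beyond 50 d |

All duration thresholds for presumed prophylaxis use the inclusive
calendar-day span of the prescription and are strict (`>`), so a 28-day
nitrofurantoin prescription is therapy and a 29-day one is prophylaxis.
The 480 mg co-trimoxazole threshold is interpreted as *total daily dose*,
matching standard prophylactic dosing (one 480 mg tablet daily).

### Numerical and tie-break choices

- Simultaneous prescription starts are ordered by `(start_ts,
  prescription_id)` for determinism; when two distinct therapy indications
  share the latest start the course is flagged `multiple_final_diagnoses`
  and excluded rather than resolved by guessing.
- A prescription without a stop date contributes its own start as its
  effective stop during linkage; when such a prescription determines the
  course end, the course stop is its start *date* (start of day, never
  end of day) and the course is flagged `truncated_missing_stop`.
- Exclusion reasons are attributed first-match in a fixed order; the
  *included set* is invariant under reordering (property-tested), only the
  attribution of overlapping reasons moves.
- Quantiles use linear interpolation between order statistics (the numpy
  default); percentages are rounded half-up to one decimal, matching how
  surveillance tables are conventionally printed.
- Validation sample sizes are `round(fraction × stratum size)` with a
  minimum of 1 for non-empty strata; draws are simple random sampling
  without replacement from a seeded generator.

## The synthetic cohort generator

`abxlot.simulate.generate` emulates the cohort structure the method was
developed against, so that the full pipeline can be tested without
hospital data:

- One admission and one treatment course per patient (readmissions only
  via the readmission scenario), admission dates uniform over a two-year
  window.
- 73% of courses community-acquired (start offset < 48 h after admission),
  the rest hospital-acquired (48–120 h).
- Indication frequencies proportional to a published per-indication
  distribution; **LOT distributions are discretized log-normals** fitted
  per indication × acquisition to published (median, Q1, Q3) triples:
  `mu = ln(median)`, `sigma = ln(Q3/Q1) / (2 z₀.₇₅)`, rounded to the
  nearest day, minimum 1, resampled (then clamped) above 45 days.  The
  log-normal family is a modelling choice — only summary statistics are
  published — and is configurable.
- 37.5% (CA) / 23.7% (HA) of courses have a post-discharge part.  Because
  a 1-day course initiated in hospital cannot outlast its discharge date,
  the indicator is drawn conditionally on LOT ≥ 2 with a probability
  inflated by the model-implied P(LOT ≥ 2), so the *marginal* fraction
  matches the configured value.  Among such courses the post-discharge
  share of LOT is drawn around 59.9% (CA) / 56.7% (HA), sd 12, clipped to
  [15, 90] and discretized to whole days.
- Noise scenarios, mutually exclusive per patient, each frequent enough to
  appear dozens of times per 1000 patients: prophylaxis-labeled overlap at
  the course start (B1, 5%), trailing unlabeled prophylaxis caught by the
  duration rule (B2, 4%), mid-course prophylaxis-labeled prescription
  (B3, 4%), missing stop date (4%), plus exclusion-cascade material —
  pediatric (3%), ICU (4%), admission < 12 h (2%), open-text indication
  (3%), multiple final diagnoses (3%), readmission mid-course (3%),
  extended course > 45 days (3%).  Real prevalences are unknown; these
  rates buy test power, not epidemiological realism.

Ground truth records, per course, the exact member prescriptions,
first/definitive indication, start/stop, LOT, acquisition, post-discharge
days and expected exclusion reason.  *Recovery* means the pipeline
reproduces all of these exactly; the test suite and the acceptance script
assert 100% recovery on seeded cohorts with all scenarios enabled.

### What the generator does not emulate

- Clinically coherent drug–indication pairing (drugs are drawn from a
  fixed therapeutic pool, deliberately disjoint from the
  presumed-prophylaxis agents so ground truth stays unambiguous).
- Transfers between hospitals, OPAT, and notes-level discrepancies: these
  exist only as reviewer-verdict inputs, never as prescription data —
  which is precisely the method's own blind spot.
- Multiple concurrent infections per patient and courses never linked to
  any admission.

Passing the recovery suite therefore shows that the *rules are
implemented exactly as specified*, not that the method is accurate on real
data; the latter is what the manual-validation workflow measures.

### Documented fidelity boundary

A trailing unlabeled prophylactic prescription whose drug is *outside*
the presumed-prophylaxis list (scenario `B2_unlisted`) is absorbed into
the course and corrupts its stop date.  The generator produces it only on
explicit request, and the test suite asserts that recovery *fails* for it
— the boundary is part of the method's documented behaviour.

## Problem sizes

The default test suite generates cohorts of 40–8000 patients (a few
seconds each); the acceptance script uses 1000 patients for the recovery
check and 4000 for cohort statistics, and finishes in well under a minute
on one CPU.  The assembly-oracle equivalence check runs 1000 random
per-patient prescription sets of up to 15 prescriptions.

## Known limitations

- The overall (all-indication) median LOT of the synthetic cohort sits at
  the 6/7-day boundary (the mixture's model-implied CDF is 0.493 at
  6 days), so seeded runs may report 6.0 or 7.0 even though every
  per-indication median stays inside its configured IQR.
- The CA/HA mix among *included* courses drifts slightly from the
  configured 73% because short-admission patients are forced CA and some
  exclusions correlate with acquisition.
- `attach_admission` links a course that starts before any admission but
  runs into one (therapy begun in the community and continued) to that
  admission with a `pre_admission` flag and classifies it CA; dropping
  such courses instead would silently miscount community-initiated
  therapy.
- Courses are never split when the registered focus changes mid-course;
  the definitive indication wins, which mirrors how the final diagnosis
  is meant to be read.
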