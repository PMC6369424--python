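# Methods

## Zone-of-control decision procedure

The engine maps a trailing window of patient self-reports to one of four
outcomes: green (in control), yellow (uncontrolled), red (dangerously
uncontrolled), or insufficient (not enough information). It is a pure
decision table, not a statistical model; all thresholds are configuration.

**Symptom component** (requires ≥ 1 in-window entry). Danger-level
symptoms anywhere in the window force red. Green requires, over the window
(default 7 days): daytime-symptom days ≤ 3, night-waking days ≤ 0,
total reliever doses ≤ 3, and no activity limitation. Anything else is
yellow. These defaults mirror the per-week control criteria used in
Canadian asthma guidelines; deployments that key off different criteria
change `SymptomCriteria`, and every test of engine structure (monotonicity,
worst-of combination, reset) is threshold-independent.

Day-level counts use *distinct local calendar days* (profile timezone,
default America/Toronto): a patient journaling three times on a bad day
contributes one symptom day. Reliever doses, by contrast, sum across
entries — dose totals are the clinically meaningful weekly quantity.

**Peak-flow component.** The most recent in-window PEF — embedded in a
journal entry or logged as a standalone measurement — is banded against
resolved thresholds: green iff PEF ≥ green_lower, red iff PEF <
yellow_lower, else yellow, with inclusive lower bounds ("90% of personal
best or better" is green). Thresholds resolve from provider-entered
absolute values (pass-through) or as fractions of the personal best
(defaults 0.90 and 0.60, configurable per deployment). A PEF older than
the window never contributes.

**Combination and insufficiency.** Available components combine worst-of —
the safety-conservative rule standard in traffic-light action plans. With
no in-window entries and no in-window PEF, or when the plan requires peak
flow but thresholds cannot be resolved, the outcome is an explicit
*insufficient* rather than a default zone: silently assuming green would
hide exactly the patients who stopped reporting.

**Reset.** Executing the action plan consumes the information that
triggered it: `apply_reset` keeps only entries strictly after the latest
reset at or before the assessment time, including entries stamped exactly
at the reset instant on the consumed side.

## Reminder rules

Emails are planned per local calendar day at the profile's reminder time
(default 19:00). Welcome: once, at enrollment. Adherence: daily while at
least one controller medication is prescribed — deliberately uncapped.
Check-in: fires on each day such that the 7 local days ending on it contain
no login, the window lies within the study, and no check-in was sent in the
previous 7 days; for continued inactivity this yields a check-in every 7th
day, and a fully inactive controller patient receives exactly
`1 + D + floor(D/7)` emails over D days. Message bodies rotate uniformly at
random over a ~30-text pool without immediate repetition (fatigue
mitigation); the rotation is a per-patient deterministic substream keyed by
(pool seed, CRC-32 of patient id), so plans do not depend on cohort
iteration order. Check-ins and adherence reminders are independent: a
check-in day still gets its adherence email.

## Analytics conventions

- **pppw** rates divide by cohort size × the full 52-week period, not by
  per-patient observed time; this matches the convention in which
  19,678 events over 123 patients and 52 weeks is 3.08 pppw.
- **Patient clocks.** Weeks (1–52) and months (1–12) are
  enrollment-relative, computed on local calendar days/dates; week 1 begins
  on the enrollment day.
- **Weekly active** = fraction of the cohort with ≥ 1 login in the given
  enrollment-relative week; the 52-vector of these is the attrition curve.
- **Good day**: a journaled local day on which *every* entry is free of
  symptom flags and reliever use (reliever use implies symptoms).
- **Rank-sum test**: the Wilcoxon rank-sum statistic is computed through
  the Mann-Whitney U (W = U + n_a(n_a+1)/2), exact when min(n_a, n_b) ≤ 10
  with no ties, otherwise normal approximation with tie and continuity
  corrections. The exact branch is verified in tests against full
  enumeration of rank partitions.
- **SUS**: 2.5 × [Σ_odd (r−1) + Σ_even (5−r)] over the 10 items; Likert
  items bucket 1–2 / 3 / 4–5 with percentages over non-missing responses,
  1-decimal rounding.
- Rates are reported at 2 decimals and percentages at 1–2 decimals in
  summaries; underlying functions return unrounded values.

## Simulator

The generator's defaults are the study conditions: 123 patients followed
for 52 weeks.

**Engagement.** The probability of being active in enrollment-relative week
w (0-based) is `p_w = p_inf + (p0 − p_inf)·exp(−λw)`, defaults p0 = 0.72,
p_inf = 0.46, λ = 0.15 per week — chosen once so that week-4 weekly-active
lands near two-thirds of the cohort and week-45 near 57%, after accounting
for the small uniform lift contributed by reminder-response logins
(response probability r per day multiplies weekly inactivity by (1−r)^7 —
an affine transform of the curve that leaves λ identifiable). The daily
login probability is `1 − (1 − p_w)^{1/7}`. An active day draws
`1 + Poisson(3.0)` accesses: printed deployment totals (~3 accesses pppw
against ~67% weekly-active) are only consistent if active users open the
platform several times a day, so multiplicity is modeled explicitly.

**Time of day.** 35% of spontaneous logins fall in a 05:00–10:00 morning
block, the rest uniformly over the day; with probability 0.03 per day a
patient logs in within 2 h after the 19:00 reminder, producing the evening
spike in the hour histogram.

**Covariates and surveillance.** A 49/122 share of patients is aged 50+,
with a 1.5× engagement multiplier normalized so the cohort mean is
unchanged; activity and reporting probabilities are multiplied by 1.5 in
the two enrollment-relative weeks ending at each clinic-visit week
(defaults 26 and 52), where a clinic_visit event is also emitted.

**Symptoms and peak flow.** A daily two-state Markov chain
(stay-controlled 0.95, stay-uncontrolled 0.85; started from its stationary
distribution, 75% controlled) drives per-day symptom draws: controlled
state P(daytime symptoms) = 0.08, night 0.02, activity 0.03, severe 0.001,
reliever ~ Poisson(0.05); uncontrolled 0.55 / 0.25 / 0.30 / 0.02 /
Poisson(0.90). This yields roughly 1.8 good days per episode day — the
mostly-controlled regime. PEF readings are personal best × state multiplier
(0.95 controlled, 0.70 uncontrolled) × (1 + N(0, 0.06)).

**Reporting.** Conditional on each login: journal 0.83, medication report
0.10, peak-flow report 0.30 — the ratios of the reported event totals to
accesses. Zone calculations are produced by running the real engine after
every journal entry (with standalone peak-flow readings supplied); after a
red assessment the patient executes the plan with probability 0.7, emitting
a reset event at noon the next day that clears the assessment window.
Emails come from running the real planner on the simulated login log.

**Randomness.** One integer seed; each patient consumes an independent
substream via `SeedSequence([seed, patient_index])`, so logs are
bit-identical across runs and per-patient behavior does not depend on
iteration order.

**What the simulator does not emulate.** No weekday/weekend structure, no
seasonality or trigger–environment coupling, no dropout distinct from
decayed engagement, no missing-not-at-random journaling tied to symptom
state, and the zone-outcome mix is not calibrated (the default conditions
give ≈ 55% green / 44% yellow / 1% red and no insufficient outcomes, since
simulated assessments always follow a fresh journal entry). Passing tests
therefore demonstrate correctness of the decision logic, planners, and
metric pipelines under controlled behavioral structure — not fidelity to
any real cohort's patient-level data, which are unpublished.

## Numerical and design choices

- **Decay fitting** (`fit_attrition_decay`): bounded least squares
  (`scipy.optimize.curve_fit`, p0/p_inf in [0,1], λ in [0,10]) initialized
  from the curve's endpoints; an exactly constant curve short-circuits to
  λ = 0 at the mean. Noise-free curves invert to < 1% relative error; on a
  simulated n = 1,000 cohort λ is recovered within 20% (in practice ≈ 1%).
  The recovery experiment neutralizes visit and age multipliers so the
  weekly-active curve is the pure decay component (boost multipliers can
  clip near probability 1 and distort the curve shape).
- **Timezones.** All stored timestamps are UTC; clock rules (reminder time,
  calendar days, hour histograms) evaluate in the profile timezone, so DST
  transitions shift the UTC send time but never the local 19:00.
- **Serialization.** Round-trip identity is defined field-for-field on
  records for both CSV and JSON-lines; log-level metadata (cohort id,
  observation window) is supplied by the caller on read. Malformed input
  fails with the line number and offending field.
- **Intervals** are half-open [start, end); zone lower bounds are
  inclusive; reset cuts are strictly-after.
- **Problem sizes in tests**: property and behavior tests run cohorts of
  6–200 patients over 4–26 weeks; the parameter-recovery experiment uses
  1,000 patients × 52 weeks; the engine/oracle grid enumerates ~24,000
  cases. The full suite completes in well under a minute of simulation
  time.

## Known limitations

- The numeric control criteria are configurable defaults consistent with
  guideline practice, not a published decision table; deployments differ.
- The AQHI message texts are asthma-oriented placeholders; the banding cut
  points (1–3 / 4–6 / 7–10 / >10) are the public Health Canada categories.
- `likert_summary` and `sus_score` assume complete item responses per
  respondent; partial SUS questionnaires are rejected rather than imputed.
- The attrition model is a three-parameter exponential; it cannot express
  the sharper-than-exponential first-month drop some deployments show.
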