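# Methods

## Scope and intent

`recallsim` models one high-volume breast imaging center at the level of a
single weekday, repeated independently: arrivals, no-shows, queueing for
shared staff/rooms/technologists/radiologists, screening recalls, and the
routing of recalled patients either to same-day diagnostic workup (the
AI-triaged workflow) or to a booked follow-up visit (the baseline
workflow). It is a scenario-comparison tool: the quantities of interest are
*differences* between scheduling templates run on common random numbers,
not absolute forecasts for any real clinic.

## Patient population and calibration

The calibrated operating point is **60 checked-in patients per weekday**,
of whom 42% receive screening mammograms (25.2/day). Scheduled volume is
therefore 60/(1−0.10) ≈ 66.7 with a 10% independent no-show probability per
appointment.

The printed category moments (means 11 / 7.1 / 7.1; SDs ≈3.1–3.3 / 2.6 /
2.6 under conventional scheduling, SD 0.3 for the fixed RSS streams) and
the ≈11% overall recall rate with ≈2.8 recalls/day are simultaneously
consistent only if those moments describe patients who actually **arrive**.
`sample_category_counts` therefore targets arrived volume: Poisson streams
are inflated by 1/(1−no-show) at scheduling (thinning a Poisson keeps it
Poisson with the target mean), while the fixed RSS category-2/3 slots are
treated as template slots kept filled from a waitlist — operationally what
"fixing the number of RSS 2 and 3 patients per day" means — and hence
exempt from no-show. With the no-show rate set to zero the generator is the
bare construction: non-RSS counts `Poisson(p_i · 25.2)`; RSS counts
`7 + Bernoulli(0.1)` (mean 7.1, SD 0.3 exactly) for categories 2–3 and
`Poisson(11)` for category 1.

Non-screening load is a documented placeholder (the true hourly type mix is
not public): screening ultrasound 10%, diagnostic imaging 38%, biopsies 10%
of checked-in volume, biopsy subtypes split evenly across
stereotactic/ultrasound/MR guidance, scheduled diagnostics reusing the
70/15/15 subtype mix. Only the screening stream drives the primary outcome;
the rest is load. In the baseline workflow the simulation's own follow-up
bookings flow back as diagnostic visits on later days, and the external
diagnostic stream is reduced by the expected arrived inflow so checked-in
volume stays calibrated across workflows.

## Arrivals

Scheduled times are drawn from a piecewise-constant hourly profile over the
9.5 h check-in window; the default is uniform — the minimal assumption,
replaceable via `ArrivalProfile(hourly_weights=...)`. Patients arrive
exactly at their slot time (no lateness model). Because the true hourly
profile is not modelled, *magnitudes* of the operational outcomes (served
within 10 h, operating hours, waits) are not comparable to any specific
clinic; only their directions and template differences are meaningful.
This is also why the test suite asserts directions, not magnitudes, for
those outcomes.

## Service processes

All service times are `Normal(mean, sd)` truncated at zero **by
resampling** (clipping would shift the mean; with the small printed SDs the
acceptance probability is ≈1, so the printed means are preserved). Each
pool (3 staff, 1 consent room, 3 dressing rooms, 5 gowned-waiting and 20
public-waiting spaces, 3 mammography technologists, 2 ultrasound
technologists, 4 radiologists/trainees) is a FIFO queue; ties in event time
resolve in scheduling order, so a fixed seed reproduces a run bit-for-bit.

Stage routing: every patient passes check-in → public waiting → dressing →
gowned waiting → examination. The consent room (capacity 1, 0.17 h) is used
by biopsy patients only: routing all 60 daily patients through it would
demand 10.2 busy-hours of a single room inside a 9.5 h window — a saturated
queue incompatible with the reported ~10.2–10.5 h operating days — so it is
modelled as procedure consent. Biopsies seize the matching technologist
plus a radiologist; MR-guided biopsies seize only the radiologist (MRI
shares no resources with the rest of the clinic and is otherwise out of
scope). Diagnostic visits end with a radiologist review (0.083 h). In the
AI workflow every completed screening mammogram triggers an AI-assessment
activity (radiologist, 0.25 h) — the radiologist-confirmation reading of
the workflow; recalled patients then receive their same-day workup and
review. The AI+radiologist decision reproduces the recall draw exactly
(100% agreement assumption): no false triage in either direction.

**Waiting time** is congestion delay only: the sum over stages of the time
between requesting a resource and seizing it. The waiting rooms' dwell
distributions are service, not waiting — so an uncongested clinic shows
exactly zero waiting, which the deterministic tests exploit.

## Recall process

Recall is drawn once per screening patient, at a rate set by the patient's
risk category: uniform (6/12/18%) or nonuniform (1/1/37%), both ≈11%
overall at the 44/28/28 category mix. A scaling knob multiplies all three
rates proportionally to hit a target overall rate (15% in the sensitivity
analysis). Baseline-workflow recalls book a follow-up visit
`Normal(20 d, 4 d)` (rounded to a positive integer day, redrawn if
non-positive) at a discrete-uniform slot in {1, …, round(0.67·60) = 40};
the slot orders the booking within the target day's diagnostic stream, and
bookings beyond the simulated horizon are recorded but not simulated.

## Randomness and common random numbers

Each (replication seed, day) pair owns six named substreams (counts, times,
no-show, recall, service, routing) derived via `SeedSequence` → Philox. All
per-patient randomness — the full possible stage-duration vector, the
recall uniform, routing uniforms, follow-up delay and slot — is pre-drawn
per day, and no-show/recall draws are indexed by screening-visit order
rather than global roster position. Consequences: (i) toggling the same-day
workflow changes only which draws are consumed, so the daily recall series
is *identical* with same-day on or off (the workflow adds no recall
mechanism) and adding the same-day pathway can delay but never accelerate
any individual patient; (ii) template pairs run with the same seeds share
arrival, no-show, recall and service streams, so their outcome differences
isolate the template.

## Outcomes

* **Recall variance**: sample variance (denominator n−1) of the daily
  recall count pooled over all replications' days (one variance per
  scenario; a per-seed variant is a one-liner on the daily frame).
* **High-recall days**: days whose recall count strictly exceeds the
  *integer-rounded* threshold `round(2 × mean)`. With mean ≈2.8 the
  threshold is 6 ("more than 6 recalls"); the rounding is what makes the
  day-count arithmetic consistent at this operating point, and the
  threshold re-derives itself under other rates.
* **Served within close**: patients whose entire visit completes by the
  10 h mark, averaged per day.
* **Operating hours**: latest completion among checked-in patients, floored
  at the 10 h close.
* **Mean wait**: congestion delay per patient, pooled over days, by default
  among patients served within close (the per-patient reported metric); an
  all-patients variant is available.

## Statistical comparisons

Levene's test (mean-centered by default; median-centered Brown-Forsythe via
a flag) compares daily-recall variances between template partners. Wilcoxon
signed-rank compares per-day series paired by (seed, day) — the only
pairing that makes days comparable, and meaningful because of common random
numbers. Wilcoxon rank-sum (via the Mann-Whitney U equivalence, midranks,
tie and continuity corrections, exact enumeration for tiny untied samples)
compares pooled per-patient waits. Degenerate inputs return p = 1 with a
warning. No multiple-testing correction is applied.

## Problem sizes

The full experiment is 8 scenarios × 365 weekdays × 10 seeds (3,650 pooled
days per scenario, ≈2 million simulated patient visits), which runs in
about 40 s on one CPU; the test suite runs the full-scale experiment and
its 15% sensitivity variant, plus reduced runs (120–300 days) where only
calibration or invariants are at stake. Monte Carlo checks use 3-standard-
error bands throughout, including the binomial band on the 5% type-I
calibration of the tests themselves.

## Known limitations

* The category-assignment decision logic combining a risk-calculator score
  with a deep-learning flag is exposed only as a user-overridable hook
  (`assign_rss_category`) with a placeholder escalation rule; default
  scenario generation samples categories from the 44/28/28 proportions
  directly.
* The hourly arrival profile, non-screening type mix and biopsy subtype
  split are placeholders; operational magnitudes inherit that uncertainty.
* No staff breaks/shifts, patient lateness, insurance denial, partial
  compliance, MRI scheduling, or batch-reading dynamics for non-flagged
  studies.
* Weekdays are a plain index (no weekend/holiday structure), and days are
  independent except for follow-up bookings.
* Under the nonuniform profile with conventional scheduling, any model in
  this class (independent per-patient recalls at an ≈11% overall rate)
  yields a daily-recall variance ≈ equal to the uniform-profile value; the
  two cannot differ materially by construction.
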