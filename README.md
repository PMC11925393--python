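# recallsim

Discrete event simulation of a high-volume breast imaging center, built to
ask one operational question: **does risk-stratified screening (RSS)
scheduling tame the day-to-day variability of mammography recalls enough to
make AI-triaged same-day diagnostic workups practical?**

After a screening mammogram, some patients are recalled for diagnostic
imaging (a potentially abnormal, BI-RADS 0 read). A clinic that wants to do
those workups *the same day* — AI flags the study, a radiologist confirms,
the patient walks to diagnostic imaging — must absorb an unpredictable
number of extra examinations with fixed technologists, radiologists and
rooms. The simulation compares two daily scheduling templates:

* **non-RSS** (conventional): every screening slot is open to anyone, so the
  daily count of each risk category is a Poisson-thinned share of volume
  (44% / 28% / 28% for 5-year cancer-risk bands <2%, 2–<4%, ≥4%);
* **RSS**: the template fixes the two higher-risk categories at 7–8 patients
  per day (mean 7.1, SD 0.3) and sequences category 3 earliest, then 2,
  then 1, so likely recalls surface early in the day.

## The model

Each weekday, a roster of ~67 scheduled patients (60 checked in after 10%
no-shows; 42% screening mammography, the rest screening ultrasound,
diagnostic imaging and biopsies) flows through check-in → waiting rooms →
examination, seizing capacity-limited shared resources (3 staff, 1 consent
room, 3 dressing rooms, 3 mammography and 2 ultrasound technologists, 4
radiologists). Service times are truncated normals; check-in stops at 9.5 h
and the clinic stays open past its nominal 10 h close until everyone
finishes.

Recall is a per-patient Bernoulli draw with category-specific rates — either
*uniform* (6/12/18%) or *nonuniform* (1/1/37%), both ≈11% overall. In the
baseline workflow a recalled patient leaves and returns ~Normal(20 d, 4 d)
later; in the AI workflow she proceeds to same-day diagnostic mammography
and/or ultrasound (70/15/15 mix) plus radiologist review.

The primary outcome is the **recall variance** — the variance of the daily
recall count over 3,650 simulated weekdays (365 days × 10 seeds). The
closed-form companion, with category counts `n_i` and rates `r_i`:

    E[R]   = Σ E[n_i] · r_i
    Var[R] = Σ E[n_i] · r_i (1 − r_i) + Σ r_i² · Var[n_i]

which makes the mechanism transparent: fixing the category-3 count removes
the dominant `r₃² Var(n₃)` term of the nonuniform profile.

## Worked example

```python
from recallsim import (analytic_oracle, count_moments, non_rss_template,
                       rss_template, nonuniform_profile, uniform_profile)

for template in (non_rss_template(), rss_template()):
    for profile in (uniform_profile(), nonuniform_profile()):
        means, variances = count_moments(template, 25.2)
        mean, var = analytic_oracle(means, variances, profile.rates)
        print(f"{template.kind:8s} {profile.name:10s} mean {mean:.2f}  variance {var:.2f}")
```

prints

```
non_rss  uniform    mean 2.78  variance 2.78
non_rss  nonuniform mean 2.79  variance 2.79
rss      uniform    mean 2.79  variance 2.46
rss      nonuniform mean 2.81  variance 1.85
```

Both templates average ~2.8 recalls/day, but the RSS template cuts the
nonuniform-profile variance from ≈2.79 to ≈1.85 (≈34%) — the same numbers
the full discrete event simulation produces within Monte Carlo error, and
the reason days with more than twice the average recall count nearly vanish
(≈12 of 3,650 vs ≈90 under conventional scheduling).

The `examples/` scripts walk through each capability (rosters, a single
simulated day, the variance oracle, the reduced scenario matrix, the 15%
recall-rate sensitivity), and a thin CLI mirrors them:

```bash
recallsim oracle --template rss --profile nonuniform
recallsim matrix --days 365 --seeds 10 --out results/
```

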