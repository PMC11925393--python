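"""The law-of-total-variance oracle for daily recall counts.

With independent category counts n_i and per-category recall rates r_i,
Var R = sum E[n_i] r_i (1 - r_i) + sum r_i^2 Var(n_i).  The closed form
explains the headline effect before any simulation: fixing the category-3
count kills the dominant r_3^2 Var(n_3) term of the nonuniform profile.
"""

from recallsim import (
    ScenarioSpec,
    analytic_oracle,
    count_moments,
    non_rss_template,
    nonuniform_profile,
    rss_template,
    run_scenario,
    uniform_profile,
)

for template in (non_rss_template(), rss_template()):
    for profile in (uniform_profile(), nonuniform_profile()):
        means, variances = count_moments(template, 25.2)
        mean, var = analytic_oracle(means, variances, profile.rates)
        print(f"{template.kind:8s} {profile.name:10s} mean {mean:.2f}  variance {var:.2f}")
# -> both templates average ~2.8 recalls/day, but the RSS template cuts the
#    nonuniform variance from ~2.79 to ~1.85 (a ~34% reduction)

spec = ScenarioSpec(template=rss_template(), profile=nonuniform_profile(),
                    days=200, seeds=(0, 1))
result = run_scenario(spec)
print(f"simulated RSS nonuniform variance over {len(result.daily)} days: "
      f"{result.summary()['recall_variance']:.2f}")
# the full simulation agrees with the closed form within Monte Carlo error
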