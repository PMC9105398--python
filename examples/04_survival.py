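"""Progression-free-interval analysis of a synthetic cohort.

Simulates 400 patients in which the 2+ high-risk-feature group carries a
planted hazard ratio of 2.0, then runs the survival layer: Kaplan-Meier
curves, the log-rank test, and a Cox proportional-hazards fit whose hazard
ratio should recover the planted effect.
"""

import numpy as np

from tilscape import (
    CohortSpec,
    cox_fit,
    km_estimate,
    logrank_test,
    select_til_sensitive,
    significance_marker,
    simulate_cohort,
)

records = simulate_cohort(CohortSpec(seed=42))
n_events = sum(r.event for r in records)
print(f"cohort: {len(records)} patients, {n_events} PFI events "
      f"({100 * n_events / len(records):.0f}%)")

sensitive = select_til_sensitive(records)
print(f"TIL-sensitive subset (ER-negative and/or LumB/Her2): "
      f"{len(sensitive)} patients")

curves = km_estimate(records, "risk_group")
for name, c in curves.items():
    t5y = c.survival[c.times <= 1825]
    print(f"  {name}: n={c.n}, events={c.n_events}, "
          f"5-year PFI {t5y[-1]:.2f}" if len(t5y) else f"  {name}: n={c.n}")

stat, p = logrank_test(records, "risk_group")
print(f"log-rank: chi2={stat:.1f}, p={p:.2e} {significance_marker(p)}")

fit = cox_fit(records, ["risk_group"])
row = fit.summary.iloc[0]
print(f"Cox HR for 2+ high-risk features: {row['hr']:.2f} "
      f"(95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f}), "
      f"p={row['p']:.2e}, concordance={fit.concordance:.2f}")
# the fitted hazard ratio should land near the planted 2.0, with the
# high-risk curve falling visibly faster; concordance ~0.6 is typical for
# a single binary risk factor.
assert row["ci_lower"] < 2.0 < row["ci_upper"]
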