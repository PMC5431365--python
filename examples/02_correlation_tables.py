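"""Summary statistics, normalization ratios and a Pearson correlation table.

Builds a small synthetic cohort with CoQ-like and CS-like variables plus one
enzyme activity, appends the activity/CS normalization ratio (on the
customary mUnits-per-CS-Units scale), and prints per-pair correlations with
their significance at p < 0.01.  Each pair uses its own pairwise-complete
subject subset, so the n column varies when cells are missing.
"""

from corrsubpop import (
    SyntheticSpec,
    correlation_table,
    normalize_ratio,
    summarize,
)
from corrsubpop.simulate import cohort_table

table, _ = cohort_table(
    SyntheticSpec(seed=7, missing_frac=0.05),
    extra_activities=("CIII",),
    activity_noise_sd=2.0,
)
table.variables = ["CoQ", "CS", "CIII"]  # the field's vocabulary

for v in table.variables:
    s = summarize(table, v)
    print(f"{v:>6}: n={s.n:3d}  range {s.min:8.1f}..{s.max:8.1f}  "
          f"mean {s.mean:7.1f}  sd {s.sd:6.1f}")

# activity per CS unit: x1000 for enzyme activities, plain ratio for CoQ/CS
table = normalize_ratio(table, "CIII", "CS")
table = normalize_ratio(table, "CoQ", "CS")

print("\npair correlations (per-pair pairwise-complete n):")
rows = correlation_table(table, [("CoQ", "CS"), ("CoQ", "CIII"), ("CS", "CIII"),
                                 ("CoQ/CS", "CIII/CS")])
for res in rows:
    flag = "*" if res.significant else " "
    print(f"  {res.x_name:>7} vs {res.y_name:<8} r = {res.r:+.3f}  "
          f"(n = {res.n}) p = {res.p:.2e} {flag}")
print("  * significant at p < 0.01")
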