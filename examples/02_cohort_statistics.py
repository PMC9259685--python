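"""Carrier-exclusion odds ratios on a case/control cohort.

Starts from published-style 2x2 counts: excludes carriers of a common mild
variant from both cohorts, then tests the association of the remaining
carriers with disease status.
"""

from paralocus.cohort_stats import (
    CohortTable,
    exclude_carriers,
    format_prevalence,
    odds_ratio_from_counts,
    prevalence,
    proportion_test,
)

# cohort with a to-be-excluded flag: 128/2325 cases, 158/1255 controls
table = CohortTable.from_counts("p.N409S", 128, 2325, 158, 1255)
table = exclude_carriers(table, "p.N409S")
for line in table.exclusion_log:
    print("#", line)

n_case = int((table.data["cohort"] == "case").sum())
n_ctrl = int((table.data["cohort"] == "control").sum())
print(f"post-exclusion denominators: {n_case} cases, {n_ctrl} controls")

# carriers of any qualifying variant after exclusion
t = CohortTable.from_counts("any_variant", 171, n_case, 43, n_ctrl)
a, b, c, d = t.counts("any_variant")
res = odds_ratio_from_counts(a, b, c, d)
p = proportion_test(a, a + b, c, c + d)
print(
    f"any_variant: {a}/{a + b} cases "
    f"({format_prevalence(prevalence(t, 'any_variant', 'case'))}%) vs "
    f"{c}/{c + d} controls "
    f"({format_prevalence(prevalence(t, 'any_variant', 'control'))}%)"
)
print(f"OR {res.or_value:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"Fisher p = {p:.3g}")
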