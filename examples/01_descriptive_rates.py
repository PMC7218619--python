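"""Descriptive Lexis-table rates: marginal pain rates by age, period and cohort.

Builds a synthetic female table with the reference structure (14 five-year age
groups 31-100, 5 periods 1991-2015) and prints the observed rate along each
margin.  Cohort rates aggregate the 18 birth diagonals; the printed labels are
birth-year spans, and the parabolic shape (interior maximum) mirrors the
generating cohort effect.
"""

from painapc import decade_cohort_labels, default_truth, generate_apc_table, observed_rates

table = generate_apc_table(default_truth("female"))
print(f"stratum: {table.stratum};  grid {table.I} ages x {table.J} periods, K={table.K} cohorts\n")

for margin in ("age", "period", "cohort", "total"):
    series = observed_rates(table, margin)
    print(f"-- {margin} --")
    for label, num, den, rate in zip(series.labels, series.numerators,
                                     series.denominators, series.rates):
        print(f"  {label:>12}  {num:>8}/{den:<8} rate={rate:.3f}")

print("\ndisjoint decade labels of the 18 overlapping diagonals:")
print(sorted(set(decade_cohort_labels(table).values())))
# A rate of e.g. 0.46 means 46% of the at-risk subjects in that margin level
# reported pain; the cohort margin peaks for mid-range birth decades.
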