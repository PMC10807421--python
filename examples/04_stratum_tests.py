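"""Testing whether an adverse event is reported unevenly across strata.

Builds the event/non-event contingency table for a fictitious event across
two sexes using vaccinated-population denominators, then applies the
selection rule: Pearson chi-squared unless the table is 2x2 with an
expected cell below 5, in which case Fisher's exact test.
"""
from otosignal.association import apply_test, stratum_event_table

# 180 events among 1.2M vaccinated males, 260 among 1.3M females
table = stratum_event_table([180, 260], [1_200_000, 1_300_000])
result = apply_test(table)
print(f"method    = {result.method.value}")
print(f"statistic = {result.statistic:.3f} (df={result.df})")
print(f"p-value   = {result.p_value:.4f}")

# small counts fall back to the exact test
small = stratum_event_table([1, 5], [60, 15])
exact = apply_test(small)
print(f"small-table method = {exact.method.value}, p = {exact.p_value:.4f}")

# A p-value below 0.05 (two-tailed) indicates the reporting rate differs
# between strata; with population-scale denominators even small absolute
# rate differences can be highly significant.
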