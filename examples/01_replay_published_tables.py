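"""Reproduce published incidence rates and shares from printed counts.

The package ships the published per-stratum report counts and CDC
vaccinated-population sample sizes for the US COVID-19 otolaryngologic
AEFI surveillance corpus (Dec 2020 - Aug 2023). Every printed incidence
rate (reports per 100,000 vaccinated persons) and percentage share follows
from those two ingredients alone.
"""
from otosignal import incidence_rate, percent_share
from otosignal.models import DoseSeries, StratumAxis
from otosignal.refdata import reference_any_counts, reference_denominators

dens = reference_denominators()
any_counts = reference_any_counts()

cps_total_reports = any_counts[(DoseSeries.CPS, StratumAxis.TOTAL, "ALL")]
cps_population = dens.lookup(DoseSeries.CPS, StratumAxis.TOTAL, "ALL")

print(f"completed primary series: {cps_total_reports:,} otolaryngologic reports")
print(f"vaccinated population:    {cps_population:,} persons")
print(f"overall incidence rate:   "
      f"{incidence_rate(cps_total_reports, cps_population):.3f} per 100,000")

tinnitus = 12_338
print(f"tinnitus: {tinnitus:,} reports -> "
      f"IR {incidence_rate(tinnitus, cps_population):.3f} per 100,000, "
      f"{percent_share(tinnitus, cps_total_reports):.2f}% of reports")

# The rate is crude (no person-time): count / population x 1e5. A value of
# 47.068 means ~47 reports per 100,000 vaccinated people over the whole
# surveillance window.
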