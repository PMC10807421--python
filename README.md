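# otosignal

Stratified incidence rates and proportional-reporting-ratio (PRR) signal
detection for spontaneous vaccine adverse-event reports, built around the
public VAERS three-file export and external vaccinated-population
denominators.

Passive surveillance systems such as VAERS collect spontaneous reports of
adverse events following immunization (AEFI) but provide no denominator, so
two complementary analyses are standard: **crude incidence rates** against
an external vaccinated-population count, and **disproportionality
analysis** against the rest of the reporting database. `otosignal`
implements both for otolaryngologic (ear/nose/throat) AEFI groups coded as
MedDRA preferred terms (PTs), together with the stratum-comparison tests
that accompany them, and a synthetic corpus generator with known ground
truth so every stage can be validated end to end.

## What it computes

For each adverse-event group *g* (a configurable set of MedDRA PTs; the
shipped default covers the 19 canonical otolaryngologic groups, from
hearing loss to pharyngitis) and each stratum (sex, age band, vaccine
manufacturer; dose series CPS = completed primary series, UBB = updated
bivalent booster):

- **Incidence rate** per 100,000 vaccinated persons,
  `IR = count / denominator × 10⁵`, with counts at report granularity
  (a report counts once per group, however many of its PTs map there).
- **Percentage share** of the stratum's total otolaryngologic reports.
- **Stratum comparison**: Pearson's chi-squared test (no continuity
  correction) on the r×2 event/non-event table built against the
  population denominators, or Fisher's exact test for 2×2 tables with an
  expected cell below 5; two-tailed, α = 0.05.
- **PRR**: with *m* reports of group *g* for the index vaccine, *n* total
  index reports, *M* and *N* the same quantities database-wide,

  ```
  PRR = (m/n) / ((M−m)/(N−n))
  95% CI = exp( ln PRR ± 1.96·√(1/m − 1/n + 1/(M−m) − 1/(N−n)) )
  ```

  with PRR ≥ 2 flagged as a signal (threshold configurable).

## Worked example

```python
from otosignal import incidence_rate, percent_share, prr, prr_ci

# published CPS corpus: 106,653 otolaryngologic reports,
# 226,593,618 people with a completed primary series
print(round(incidence_rate(106_653, 226_593_618), 3))   # 47.068 per 100,000
print(round(incidence_rate(12_338, 226_593_618), 3))    # 5.445  (tinnitus)
print(round(percent_share(71_255, 106_653), 2))         # 66.81  (dizziness share, %)

print(prr(10, 100, 20, 300))                            # 2.0
print(tuple(round(x, 3) for x in prr_ci(10, 100, 20, 300)))  # (0.861, 4.647)
```

The first three numbers are the published overall, tinnitus and dizziness
figures for the completed-primary-series corpus, reproduced from printed
counts and sample sizes alone. The PRR example shows an index-vaccine
reporting share twice the background share; the wide interval reflects
m = 10 events.

Runnable narrative scripts live in `examples/` (table replay, simulate +
full pipeline, PRR arithmetic, stratum tests), and the pipeline is also
available from the shell:

```bash
otosignal simulate --seed 42 --out sim/
otosignal run --reports-data sim/DATA.csv --reports-vax sim/VAX.csv \
    --reports-symptoms sim/SYMPTOMS.csv --denominators sim/denominators.csv \
    --mapping sim/groups.yaml --series cps --out results/
```

writing `table1_sex.tsv`, `table2_age.tsv`, `table3_manufacturer.tsv`,
`table4_prr.tsv` and a reproducibility manifest.

## Layout

- `src/otosignal/vaers_io.py` — VAERS-dialect readers, denominator and
  mapping configs, TSV writers
- `src/otosignal/pt_grouping.py` — PT → group assignment and report selection
- `src/otosignal/incidence.py` — stratified counts, shares, rates
- `src/otosignal/association.py` — chi-squared / Fisher machinery
- `src/otosignal/disproportionality.py` — PRR, intervals, signal flags
- `src/otosignal/synthetic.py` — corpus generator and ground truth
- `src/otosignal/refdata.py` — published replay fixture
- `src/otosignal/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the statistical model, its assumptions and
limitations.
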