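# Methods

## Setting and counting unit

The package analyses spontaneous adverse-event-following-immunization
(AEFI) reports in the public VAERS three-file layout (demographics,
vaccine records, MedDRA preferred-term symptom rows, joined on the report
id). The counting unit throughout is the **report**, not the person:
passive surveillance cannot link multiple reports from one individual, so
"incidence" here means reports per vaccinated population, and one person
reporting twice counts twice. Symptom rows for the same report id are
merged by set union before any counting.

Reports are assigned to a denominator series by vaccine type: a bivalent
booster record (`COVID19-2`) puts the report in the UBB (updated bivalent
booster) series and supersedes any primary-series record on the same
report; otherwise a `COVID19` record puts it in CPS (completed primary
series). Reports that also carry a non-COVID vaccine type remain index
reports. The dose-number column is carried through but not used as a
filter, since series membership is already encoded in the vaccine type of
the source extracts.

## Group assignment

Each MedDRA preferred term maps to at most one of a configured list of
adverse-event groups (default: the 19 canonical otolaryngologic groups).
A report counts **once per group** regardless of how many of its PTs land
in that group, and contributes to **every** group it maps to — exclusivity
is not forced, though in practice co-occurrence is rare enough that group
shares sum to roughly 100%. A PT listed under two groups is a
configuration error; an unmapped PT is dropped (or raises, under the
strict policy). The shipped default mapping seeds each group with the
terms literally named in its label plus immediate spelling variants;
a full curated PT list should be supplied as config for production use.

## Incidence rates, shares and denominators

For group g in stratum s:

    IR(g, s)  = count(g, s) / persons(s) × 100,000
    pct(g, s) = count(g, s) / count(ANY, s) × 100

where `ANY` counts reports with at least one mapped group and `persons(s)`
comes from an external denominator table (emulating the CDC COVID Data
Tracker populations). Rates are crude: no person-time, no
age-standardization, matching how such surveillance figures are published.

Conventions, chosen to match the published tables exactly:

- Age bands are half-open integer-year intervals [0,18), [18,50),
  [50,65), [65,∞) labelled `0-17, 18-49, 50-64, 65+`.
- Reports with an unknown level on an axis are excluded from that axis's
  level rows but kept in the TOTAL row, so level counts need not sum to
  the total when missingness is present.
- No per-manufacturer primary-series populations are published, so the
  MANUFACTURER axis uses the at-least-one-dose (ALOD) denominators while
  counts stay series-scoped; manufacturer levels with no published
  denominator for a series (Janssen under UBB, never authorized as a
  bivalent booster) are omitted.
- Denominator tables publish levels and totals independently; a level sum
  below the total is tolerated with a logged note (the published age
  populations do not sum to the overall population), but a level sum
  exceeding its total is rejected.
- Display rounding is 3 decimals for IRs, 2 for shares, half-even;
  p-values below 0.001 print as `<0.001`. Internal arithmetic is full
  precision.

The package ships the published counts and sample sizes of the US
COVID-19 otolaryngologic surveillance corpus (Dec 2020 – Aug 2023) as a
replay fixture; the test suite verifies that all 707 printed rate and
share cells reproduce to printed rounding. One published cell (the UBB
hearing-loss total, printed count 19 against an IR and a male+female sum
both implying ≈196) is internally inconsistent and flagged as a misprint
in `refdata.MISPRINT_CELLS`, excluded from replay checks.

## Stratum comparison tests

For each group and axis, an r×2 table of (event reports, stratum
population − event reports) is tested for homogeneity across levels.
Selection rule (the Cochran criterion, stated explicitly since published
analyses often leave it implicit): Fisher's exact test iff the table is
2×2 and any expected cell is below 5; otherwise Pearson's chi-squared
without continuity correction. All tests are two-tailed at α = 0.05, with
no multiple-testing correction across the ~19 groups × 3 axes (a
deliberate mirror of standard surveillance practice; interpret p-values
accordingly). Event counts are tiny relative to population denominators,
so tables are held as 64-bit integers.

Fisher's two-sided p sums, over the hypergeometric support fixed by the
observed margins, the probabilities of all tables no more likely than the
one observed, with a 1e-7 relative tie tolerance (the convention of R's
`fisher.test`). The pmf is evaluated via log-gamma; the test suite checks
the implementation exactly against a rational-arithmetic enumeration
oracle on every 2×2 table with N ≤ 60 (635,375 tables) and against an
independent library implementation on random tables.

## Disproportionality (PRR)

With m = index-vaccine reports of the group, n = all index-vaccine
reports, M and N the same counts over the entire database (index +
background), the proportional reporting ratio is

    PRR = (m/n) / ((M−m)/(N−n))

and its 95% interval the standard log-normal (delta-method) one,

    exp( ln PRR ± z₀.₉₇₅ · √(1/m − 1/n + 1/(M−m) − 1/(N−n)) ).

A PRR ≥ 2 flags a signal. Design choices:

- The bare ≥ 2 threshold is the default; the classical auxiliary criteria
  (m ≥ 3 and chi-squared ≥ 4) are available behind a flag, off by default.
- m = 0 yields PRR 0 with an undefined interval rather than an error.
- A group absent from the background (M−m = 0) has no finite PRR: the
  scalar operation raises unless a continuity correction (+0.5 on the
  four derived cells) is enabled; the table builder skips such groups
  with a warning so that small-corpus runs complete.
- In the pipeline, n is the number of index-vaccine reports in the loaded
  corpus and N−n the number of background reports; m and M−m are mapped
  group counts. A signal is a reporting disproportion, not a causal claim,
  and PRRs are only comparable within one database snapshot.

Empirical properties verified by the suite at study-scale conditions:
planted reporting-rate ratios are recovered within three standard errors
seed by seed; the interval's coverage of a true ratio of 2 over 1,000
binomial replicates (expected m = 60) lies in [92%, 98%]; on null corpora
with expected group counts ≥ 50 fewer than 7% of groups are flagged; the
chi-squared test rejects 5% ± 1.5% of null replicates at α = 0.05.

## Synthetic corpus generator

`synthetic.generate` emits the three report files, a denominator table, a
matching PT→group mapping and a ground-truth JSON, deterministically from
a seed (byte-identical reruns). Each report draws a sex, an integer age
within a drawn band (65+ is sampled on 65–89), and a manufacturer from a
configurable mix; each group is then included independently with its
configured probability (times a planted multiplier for index reports,
capped at 1 with a recorded warning), emitting 1–k synonym PTs to
exercise per-report deduplication; reports with no group get an unmapped
filler PT. Background reports carry a non-COVID vaccine type so the
standard loader filter separates the corpora.

Defaults emulate the published corpus: group probabilities are the
published CPS group shares; background probabilities are those shares
deflated by the published PRRs; the sex/age/manufacturer mix follows the
published report distribution; denominators are the published population
sample sizes; missingness defaults to 0 so stratum-sum invariants hold
exactly. Default corpus sizes (20,000 index / 40,000 background reports)
are a deliberate scale-down of the ~10⁵-report study corpus that keeps
expected counts per group large enough for the asymptotics being tested;
tests that need specific conditions (single group, planted ratio 2, null
uniform groups) configure them explicitly.

What the generator does **not** model — and hence what passing tests do
not establish about real data: reporting biases and their dynamics over
time, duplicate or linked reports from one person, PT co-occurrence
structure beyond an optional pairwise boost, stratum-dependent reporting
propensity, and narrative-text screening (a human curation step). The
generator validates the *machinery*, not the epidemiology.

## Known limitations

- Crude report-based rates against population denominators understate
  true incidence (underreporting) and cannot support causal claims.
- Only univariate stratifications are implemented, as only disaggregated
  one-way denominators are published.
- The printed p-values of the source tables are not reproduced as
  acceptance values: several are internally inconsistent (apparent
  column-shift repeats of adjacent rate values), and the exact corpus
  behind them is not recoverable from printed numbers alone.
- Published PRRs cannot be reproduced exactly because the database-wide
  background totals M and N were not published; the PRR stage is instead
  validated by exact arithmetic oracles and parameter-recovery simulation.
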