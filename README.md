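# pvsignal

Disproportionality-based adverse-event signal detection for FAERS-style
spontaneous-report databases.

Post-marketing surveillance databases such as the FDA Adverse Event
Reporting System (FAERS) collect voluntary case reports: a patient, one or
more drugs with suspect-role codes, and one or more adverse reactions coded
as MedDRA preferred terms (PT), each PT belonging to a system organ class
(SOC). Because there is no denominator of exposed patients, safety signals
are found by *disproportionality*: comparing how often a drug–event pair is
reported against how often it would be reported if drug and event were
independent across the database. `pvsignal` packages that workflow — built
around the analysis of esketamine nasal spray reports — for
pharmacovigilance analysts and methods researchers: loading and cleaning
report data, building the 2×2 tables, computing the classical statistics
with confidence intervals, screening against thresholds, and summarizing
results, plus a synthetic-report generator with ground-truth bookkeeping so
every stage is testable without any download.

## The statistics

For one drug–event pair the database partitions into the four-grid

|                  | target event | other events |
|------------------|--------------|--------------|
| target drug      | a            | b            |
| other drugs      | c            | d            |

with N = a+b+c+d, and the package computes:

- **ROR** (reporting odds ratio) = ad/bc, with Woolf's log-normal interval
  exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d));
- **PRR** (proportional reporting ratio) = (a/(a+b)) / (c/(c+d)), interval
  exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)));
- **EBGM**, in two variants selected by `ebgm_mode`: the unshrunk relative
  reporting ratio a·N/((a+c)(a+b)) with a log-normal interval
  (`"unshrunk"`, the default), or a DuMouchel-style gamma-Poisson
  shrinkage estimate with EB05/EB95 posterior quantiles (`"mgps"`);
- Pearson **χ²**, Yates-corrected by default.

A pair is screened as a **signal** when a ≥ 3 with the ROR and PRR interval
lower limits above 1, and EBGM05 above 2 (all three by default;
configurable via `SignalCriteria`).

Cleaning follows standard FAERS practice: reports dated before the target
product's marketing date (2019-03-05 by default) are dropped, and
duplicates are removed in two stages — among versions of one case only the
highest version survives, then distinct cases identical on (sex, age group,
country, event date, PT multiset, seriousness) collapse to the most
recently received one.

## Worked example

```python
from pvsignal import clean, default_config, generate_database, screen_signals, top_signals

cfg = default_config(n_reports=5000, seed=7)   # two implanted pairs at rate ratio 20
db, ledger = generate_database(cfg)
cleaned, audit = clean(db)
result = screen_signals(cleaned, "esketamine")
for s in top_signals(result, k=10):
    print(s.term, s.n, round(s.ror.point, 2), round(s.ebgm.ci_low, 2))
```

which prints (seed 7):

```
generated 5250 reports (250 injected duplicates, 100 dated before the cutoff)
cleaning: 5250 -> 4900 reports (250 duplicates removed)

20 event terms screened; signals:
  Dissociation         n=  82  ROR= 21.96 [15.63,  30.85]  EBGM=  8.63 (EBGM05= 6.14)
  Sedation             n=  61  ROR= 13.73 [ 9.64,  19.56]  EBGM=  7.03 (EBGM05= 4.93)
```

The generator implanted exactly these two pairs at a reporting rate ratio
of 20; the other 18 terms follow drug–event independence and none of them
passes the screen. `n` is the a-cell, the bracketed pair is the 95% ROR
interval, and EBGM05 is the screening lower bound. Run
`python examples/simulate_and_screen.py` for this output, and see the other
scripts in `examples/` for loading quarterly ASCII files, recomputing
summary-table percentages, and empirical-Bayes shrinkage.

A thin CLI mirrors the pipeline (`pvsignal simulate | clean | tabulate |
screen | report`); run `pvsignal --help`.

## Layout

- `pvsignal.types`, `pvsignal.io`, `pvsignal.meddra` — report model, FAERS
  quarterly ASCII / dashboard CSV readers and writer, bundled PT→SOC table
- `pvsignal.preprocessing` — date filter, target-drug restriction, dedup
- `pvsignal.contingency` — four-grid construction (event-record or case unit)
- `pvsignal.disproportionality` — ROR/PRR/EBGM/χ², criteria, screening
- `pvsignal.mgps` — gamma-Poisson shrinker (prior fit, posterior EBGM)
- `pvsignal.reporting` — demographic, SOC and top-N summary tables
- `pvsignal.synthetic` — generator, ground-truth ledger, closed-form
  expected cells, recovery experiments

`docs/methods.md` documents the model assumptions, parameter choices and
known limitations.
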