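# Methods

## Setting and assumptions

Spontaneous-report databases have no exposure denominator, so all inference
here is *within-database*: a drug–event pair is compared against the rest of
the same database under the working assumption that, absent an association,
the event's share of a drug's reports matches its share of everyone else's
reports. Nothing in these statistics estimates incidence; a "signal" is a
disproportion worth review, not evidence of causation. Reporting biases
(stimulated reporting, channeling, duplicate submissions) are handled only
to the extent the cleaning stages below remove them.

## Counting model

The analysis unit is configurable and matters more than it looks:

- **event-record unit** (default): each (case, PT) pair is one countable
  record, after collapsing identical PTs within a case. A case with three
  distinct reactions contributes three records. Row margins a+b equal the
  target drug's total reaction records. Published SOC-level percentage
  tables use this denominator.
- **case unit**: each case counts once; a case with the event goes to cell
  a only. Demographic tables use this denominator.

Both units are exposed everywhere (`counting_unit=`), and the reporting
module deliberately mixes them the way published summary tables do: the
demographics block is per case, the SOC block per reaction record, each
output labelling its denominator. SOC-level contingency tables collapse
multiple PTs of one SOC within a case to a single record, so a case never
contributes twice to one SOC cell; consequently SOC tables are *not* the
sum of their PT tables.

A report is a "target" report when it names the target ingredient with the
primary-suspect role code (configurable). Drug names are matched after
case-folding and punctuation stripping, and a product name (e.g. a brand
name) matches as well as the active ingredient.

## Cleaning

1. **Date filter** — reports dated strictly before the cutoff
   (default 2019-03-05, the target product's first marketing date) are
   removed. Reports carrying only a received year are kept iff that year is
   at least the cutoff year: year-level data cannot be placed within the
   cutoff year, and dropping the whole year would discard the launch year's
   reports.
2. **Reaction-free drop** — reports with zero coded reactions are
   unanalyzable and removed (counted in the audit trail).
3. **Deduplication** — two stages, both deterministic and order-invariant:
   (i) among reports sharing a case id, the highest version wins;
   (ii) among distinct case ids, reports identical on the tuple (sex, age
   group, country, event date, sorted PT multiset, seriousness) collapse to
   the most recently received, ties to the lexicographically smallest case
   id. Stage (ii) can be switched off (`mode="version"`) because practice
   varies on how aggressive cross-case collapsing should be; the full rule
   is the default. No probabilistic record linkage is attempted.

The pipeline (`clean`) returns an audit dataclass with input, post-filter,
duplicates-removed and output counts.

## Estimators and numerical choices

ROR, PRR and the unshrunk EBGM (relative reporting ratio) are computed
exactly as printed in the README with z = 1.96 by default; a confidence
level can be supplied instead and z is recomputed from the normal quantile.
Zero cells leave a statistic undefined rather than silently corrected —
an undefined statistic fails its screening flag — because the thresholds
were defined without a continuity correction; Haldane's +0.5 on all cells
is available by flag. χ² is Yates-corrected Pearson by default (the
conventional companion to PRR screening), floored at zero when the
correction exceeds |ad − bc|; the uncorrected variant is a flag away and is
cross-checked against an independent contingency-test routine in the tests.

The screening thresholds (a ≥ 3; ROR and PRR CI lower limits > 1; EBGM05
> 2) are data, not code: `SignalCriteria` carries them, and the combination
is a conjunction by default (`combine="all"`) with `"any"` available. No
multiplicity adjustment is applied by default, matching screening practice;
the false-flag rate under the null is instead quantified by simulation.

### Gamma-Poisson shrinkage (MGPS)

The shrunk EBGM models each cell's count as Poisson(λE) with E the
independence expectation and λ drawn from a two-component gamma mixture
(shape/rate (α₁, β₁), (α₂, β₂), weight w). The marginal is a two-component
negative-binomial mixture; its five parameters are fitted by maximum
likelihood over all drug–event cells of the database (every
primary-suspect ingredient, not only the target drug — the prior describes
the database, and also needs the ≥50 cells the fit requires). The optimizer
is L-BFGS-B on log/logit-transformed parameters from a fixed eight-point
multi-start grid; the fit is deterministic and permutation-invariant up to
floating-point summation order. Bounds of ±12 on the log scale keep the
components proper; degenerate data (e.g. all cells exactly at expectation)
push both components to a spike at λ = 1, which is the correct limit.

The posterior given (a, E) is again a two-gamma mixture; EBGM is
exp(E[ln λ]) computed in closed form with the digamma function, and
EB05/EB95 are mixture-CDF quantiles found by bracketed root finding
(tolerance 1e-8) between the component quantiles, with degenerate-weight
edge cases short-circuited.

Two properties deserve a caveat. Shrinkage pulls estimates toward the
*fitted* prior's geometric mean, which finite data place O(1/√cells) away
from exactly 1 (about 0.004 at 5,000 null cells); cells whose raw ratio is
already closer to 1 than that offset end up at the fitted center, so the
inequality |ln EBGM| ≤ |ln obs/exp| holds only up to that offset, and the
tests assert exactly that form. Similarly, the unshrunk ratio
a·N/((a+c)(a+b)) is strictly increasing in a only while the background cell
d dominates — the usual regime, since one drug's reports are a sliver of
the database — and the monotonicity tests restrict to it.

## Synthetic data: what it emulates and what it does not

The generator draws independent reports: drugs by per-drug marginal
probabilities with at least one drug per report, a primary-suspect role by
per-drug probability, reactions by per-PT marginals with at least one
reaction per report, demographics from categorical distributions. The
"at least one" constraints are implemented by redraw, i.e. the realized
distribution is the independent one conditioned on non-emptiness, and the
closed-form expected-cell oracle (`expected_contingency`) applies exactly
that conditioning, by enumeration over drug presence and suspect-role
states. Signals are implanted multiplicatively — when an implanted pair's
drug is primary suspect on a report, that PT's probability is multiplied by
the rate ratio and capped at 1 — and the ledger records the post-cap
effective ratio, keeping the oracle exact. With a single implanted pair
the expected-cell ROR equals the effective rate ratio; with several pairs
on one drug the b cell inflates and the expected ROR falls below it, which
the oracle reproduces.

Duplicates are injected by cloning a uniform sample of post-cutoff reports
under fresh case ids (sorting after the originals, so dedup keeps the
original); a configured fraction of reports receives an event date before
the cutoff. Original reports are guaranteed pairwise distinct on the dedup
tuple (colliding event dates are resampled within the seeded stream), so
the cleaning pipeline removes *exactly* the ledger-listed records — this is
what makes the bookkeeping tests exact rather than statistical.

Everything is a pure function of the config, including its seed.

Default study conditions (`default_config`): 10,000 reports; one target
antidepressant (marginal 0.06, primary-suspect probability 0.8) among seven
common psychiatric co-medications (marginals 0.10–0.25); twenty PTs across
eleven SOCs with marginals 0.005–0.08; demographics mirroring a typical
spontaneous-report mix (53% female, 60% serious, 80% US, 79% healthcare-
professional reporters, years 2019–2023 with increasing volume); 5%
duplicate contamination; 2% pre-cutoff reports; the target drug's two
hallmark reactions implanted at rate ratio 20. Tests scale `n_reports`
between 600 and 10,000 depending on what the check needs.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: drug co-prescription correlation (drugs are
independent given the report), indication channeling, reporting-rate drift
over calendar time, free-text verbatim terms and coding noise, partially
overlapping duplicates that differ on the dedup tuple, and missingness
that is informative rather than random.

## Validation surfaces

- Estimator formulas agree to 1e-9 with independently computed
  high-precision evaluations of the printed formulas, and with
  statsmodels' 2×2 odds-ratio interval at the exact normal quantile.
- The 95% ROR interval covers the null in 95% ± 1.5% of 2,000
  independence simulations at N = 20,000.
- On databases with five implanted rate-ratio-20 pairs sized so the
  expected a-cell is ≈33 (n = 2,800 reports), detection power is 1.0
  across 50 replicate seeds and the null false-flag rate is below 5%.
- The MGPS posterior matches the single-gamma digamma closed form to
  1e-10; prior refits on 50,000 simulated cells reproduce the true prior's
  EBGM functionals within 5%.
- Published demographic and SOC percentages are recomputed exactly from
  their printed count tables through the summary operations
  (`scripts/acceptance.py`).

## Known limitations

- The published per-term ROR/PRR/EBGM values for the seed analysis are not
  reproducible from this package alone: they depend on the full FAERS
  background (over 10 million reports), whose extract is not
  redistributable here, and the published table is not exactly consistent
  with any single counting unit. The package therefore validates the
  machinery on synthetic ground truth instead.
- The bundled PT→SOC table is a miniature fixture (~100 terms), not the
  licensed MedDRA dictionary; unknown PTs map to the sentinel SOC
  "Unmapped" rather than failing.
- Stratified (age/sex/year) contingency tables, Bayesian IC/BCPNN, and
  regression-based signal detection are out of scope.
- The dashboard CSV reader's version heuristic (trailing digit of an
  all-numeric case id) follows the FAERS primaryid convention but cannot be
  verified for arbitrary exports; supply an explicit version column when
  one exists.
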