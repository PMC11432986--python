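# Methods

## Design

`sedror` implements a case/non-case (disproportionality) analysis on
spontaneous-report line listings. The unit of analysis for estimation is
the *event*: for each exposure group, `a` counts events coded with a
target MedDRA Preferred Term across all retained reports of that group and
`b` counts every other event those reports carry. This full-dataset event
counting is a deliberate reading: it is the only one under which the
narrow confidence intervals seen in practice for contrasts with a few
dozen target events are attainable (they require `b`, `d` in the hundreds
to thousands), and it matches the textbook definition of the ROR cells.
Case *reports* (used for the descriptive tables) are those with at least
one target-term event.

Exposure groups are the seven non-empty subsets of
{dexmedetomidine, midazolam, propofol} found among a report's *suspect*
drugs. Suspect drugs outside the trio (co-suspects) do not move a report
between groups; concomitant drugs never affect grouping. The partition is
exhaustive and mutually exclusive; reports with no study sedative among
suspects fall into `NONE` and are excluded from group tables.

## Estimator

ROR = ad/bc with the Woolf CI `exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d))`,
z = 1.96 by default (the conventional rounded quantile; tests that
cross-check against statsmodels pass the exact 0.975 quantile instead).
Gating: no estimate when `a < 3` or `c < 3` — the minimum-events rule
applied to the target-event count on each side. Zero cells surviving the
gate (possible for `b`/`d`, or for `a`/`c` when the gate is relaxed) get
the Haldane–Anscombe +0.5 added to all four cells, flagged in the output.
Significance is "95% CI excludes 1", identical to the two-sided Wald test
on log ROR at α = 0.05; the Wald p-value is emitted for transparency. No
multiplicity adjustment is applied anywhere.

The comparison plan covers: the lead drug (DEX) against each of the six
other groups; the sub-analysis pairs MID vs PRO, DEX/MID vs each
higher-order combination, DEX/PRO vs MID/PRO and vs DEX/MID/PRO, MID/PRO
vs DEX/MID/PRO; all of the above under both the primary term set (the
single target PT) and the indicative set; and male-vs-female contrasts
within DEX, MID and PRO under both term sets (reports with unspecified sex
are excluded from sex strata; full-dataset event denominators are used for
consistency with the main analysis).

## Term sets

The primary case definition is the single PT "Rhabdomyolysis". The
default indicative set extends it with myoglobin markers (myoglobinuria,
blood/urine myoglobin findings), muscle-enzyme and transaminase
elevations (CPK, LDH, AST, ALT), muscle signs and symptoms (myalgia,
muscular weakness, muscle necrosis), chromaturia and oliguria. This
default is an explicit curation — regulatory sign/symptom appendices vary —
and is fully overridable from a one-PT-per-line text file. Matching is
exact on the whitespace-normalized, case-folded PT name; no MedDRA
hierarchy (HLT/HLGT) expansion is attempted, and the bundled PT→SOC
vocabulary is a small curated subset, not the licensed dictionary.

## Deduplication

Public line listings carry no stable worldwide case identifiers, so the
duplicate key is a heuristic: (sex, age band, region, sorted suspect
names, sorted PT multiset); identical case ids always collapse; the first
occurrence wins. The pass is idempotent. Known limitation: on datasets
with low per-report entropy — coarse demographics and short event lists —
genuinely distinct reports can share a key and be over-merged. The
margin-reconstructed case-series fixture is the extreme case (it contains
structurally identical reports because only table margins are published),
which is why the pipeline exposes `dedup: bool` and fixture-based analyses
run with deduplication off; the fixture is duplicate-free by construction.

## Descriptive conventions

* Seriousness: each event carries a set of ICH E2D criteria; tables use
  the single most serious one under the fixed total order death >
  life-threatening > disabling > hospitalization > congenital anomaly >
  other medically important > not serious. The order between
  hospitalization and congenital anomaly is this package's choice; the
  published tables only ever show already-resolved single criteria, so no
  printed cell depends on it.
* Outcome: recovered/resolved and recovering/resolving are favourable;
  recovered with sequelae, not recovered and fatal are unfavourable;
  unknown stays unknown.
* Percentages: half-up rounding to one decimal, computed at render time
  from full-precision counts. Denominators: reports per group for
  demographics; target events per group for seriousness/outcome (equal to
  report counts when each case carries exactly one target event);
  non-target events per group for the SOC block; concomitant drug entries
  for the ATC block (classified by ATC level-2 prefix: N01 anaesthetics,
  N02 analgesics, N05 psycholeptics, other, unclassified when no code).
* Region has no "not specified" level in the line-listing dialect;
  unknown region strings fall to non-EEA as the residual class, with a
  logged warning.

## Synthetic-data generator

Per report in group g with parameters (p, λ): one index event that is the
target PT with probability p and a background PT otherwise, plus
K ~ Poisson(λ) further background events, all drawn with PT-independent
seriousness and outcome from configurable categorical margins. Expected
target events per report are p and expected other events (1−p)+λ, so the
true ROR of any pair of groups is the ratio of their per-report odds
p/((1−p)+λ) — recorded, together with realized counts, in a truth ledger.
Exactly one target event per report (no within-report repeats), matching
case series where case counts equal target-event counts.

Defaults are the study conditions the package emulates: demographic,
seriousness and outcome margins equal to the published overall case-series
margins; seven groups at full-extract scale (19,268 reports total, sizes
2000/5000/10000/300/500/1400/68) with p chosen so expected target events
match the published per-group case counts; λ = 3 background events per
report (typical multi-event intensive-care reports); a co-suspect added
with probability 0.62 (the published share of cases not exclusively
reporting a study sedative) and a concomitant with probability 0.544 (the
published share with ≥1 concomitant); duplicate_rate 0 (duplicates are
injected explicitly, as copies under fresh case ids, count =
round(rate·n)). What the generator does **not** emulate: reporting-rate
dynamics over calendar time, drug–event causality structure, correlated
demographics, within-report PT co-occurrence patterns, and free-text or
date-based duplicate signatures. Passing tests therefore demonstrate the
statistical machinery on data with the assumed structure, not the data
quality of any real spontaneous-reporting database.

The deterministic 364-report fixture reconstructs the published case
series: per-group demographic, seriousness and outcome margins cell for
cell, plus the published per-SOC non-target event counts (1446 events;
1810 events in total). Only margins are published, so the within-group
joint assignment is a fixed round-robin over the margin expansions, with
PT choice rotating through each SOC's vocabulary pool — deterministic and
margin-exact; any margin-consistent joint would be equally valid.
Concomitant-drug margins are left unreproduced (the published rows are
internally inconsistent with their column totals).

## Numerical and scale choices

All randomness flows through one `numpy` Generator seeded from the config;
identical seeds give bit-identical datasets. The acceptance script and
test suite size their Monte Carlo checks as 200 replicates, with 2000
reports per group under the null (type-I error ≈ 5%, judged with a
3-sigma binomial band) and 5000 per group for coverage of a true ROR of
3.0 (expected ≈ 95%, required ≥ 93%). The p for the ROR-3 design is 6/41 against 0.05 at
λ = 3, which makes the true ROR exactly 3. Internal tables keep full
precision; rounding happens only in rendered output.

## Limitations

Spontaneous-report disproportionality measures reporting, not risk:
underreporting, stimulated reporting and confounding by indication are
untouched by this package. The ROR here is crude (no stratified or
regression-adjusted variant), duplicates are matched heuristically rather
than by probabilistic linkage, and the bundled vocabulary is a working
subset. Date-window filtering applies only when receipt dates are present
in the listing (assumed pre-windowed otherwise).
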