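# Methods

## The reporting-system model

A reporting system is a list of **levels** with explicit integer ranks
(community = 0 upward) and roles (`community`, `facility`,
`intermediate`, `terminal`), a set of **sites** each attached to a
level and to one or more parents at strictly higher ranks, level-level
**flow edges**, and **indicator definitions** that tie a report field
to an illness and (for treatment indicators) to a register validation
rule. Ranks are declared, never inferred from edge order: real systems
differ enough (parallel terminal branches, systems with no national
edge at all) that inference is ambiguous. Parallel terminal stores —
e.g. a national HIS *and* an implementing partner database — are
modeled as multiple terminal levels; tracing runs once per terminal,
and a site's routing path to a given terminal picks the lowest-id
parent whose closure reaches it, so paths are deterministic.

Community sites reporting to more than one facility are rejected by
default (`allow_multi_parent_community` opts in); the common program
design attaches each CHW to a single supervising facility, and silent
multi-parenting would double-count registers in a trace.

A site's activity is period-scoped through an optional activity
calendar (default: active throughout). Expected reports per site =
active months × the level's reports-per-month (default 1, i.e. monthly
reporting). This matters because DQA practice excludes CHWs who were
not active for the full reporting period.

## Register verification

A validation rule names the treatment codes it covers and a boolean
evidence expression over declared symptom/diagnostic codes, written in
a small YAML grammar (`all`, `any`, `present`, `eq`, `ge`, `age_lt`,
`age_ge`). Codes are validated against the registry at load time, so
an undeclared code is a configuration error, never a runtime surprise.
The shipped defaults follow standard iCCM case definitions and are
configuration, not code:

- malaria: fever recorded **and** RDT result positive (treatment: ACT);
- diarrhea: diarrhea symptom recorded (treatments: ORS, zinc);
- pneumonia: cough recorded **and** (fast-breathing ticked **or**
  respiratory rate ≥ 50/min under 12 months, ≥ 40/min at 12–59 months)
  (treatment: amoxicillin).

The verification ratio is `recorded / appropriate` by default, so a
worse register reads > 1, pointing the same way as the
consistency-ratio under-reporting convention; the reciprocal
orientation is available via a flag. `0/0` yields a not-applicable
sentinel and `x/0` a flagged infinity — empty registers are data, not
exceptions. Entries are filtered to the assessment period by encounter
date, closed on month boundaries.

## Data tracing

For each facility, the trace row is the sequence
`(register recount, community summary total, facility total, …,
terminal total)`. Two conventions are fixed and deliberately opposite:

- **differences** subtract upward (`level k+1 − level k`; end-to-end =
  terminal − register), matching how counts-and-differences tables are
  printed, and telescoping: the end-to-end difference equals the sum of
  stepwise differences whenever all counts are present;
- **consistency ratios** divide downward (`lower / higher`), so 1 means
  agreement, > 1 under-reporting, < 1 over-reporting.

Counts attributable to a facility above the facility level are read
from per-facility rows in the higher level's records (the
`about_site_id` column), mirroring how a DQA team extracts
facility-specific values from a district ledger or the HIS.

Missing handling: a report that exists but leaves the indicator blank
makes the whole cell missing (you cannot total a form that is not
filled); a cell with *no* matching reports at all is missing too; but
when only some of a cell's contributing reports are absent, the present
ones are summed — a recount of the forms physically available is
exactly what a field team does, and lost reports then surface as
discrepancy, which is the phenomenon being measured (their absence per
se is availability's business). Missing cells are never coerced to 0;
rows stay in the table flagged, and the aggregate consistency ratio for
a level pair is the **ratio of sums** over rows where both counts are
present (per-row ratios are also emitted) — aggregating the ratio of
sums rather than the mean of ratios matches comparing a facility report
against the sum of its CHWs' reports.

Completeness uses expected reports as its denominator by default, which
makes `pct_complete ≤ pct_available` a checkable invariant; a flag
switches to available-as-denominator. Timeliness is only reported when
every report in scope carries a submission date; otherwise the level is
flagged *not assessable* — partial percentages over self-selected dated
reports would be biased.

## Systems assessment

Scores are 1–3 (no / partly / completely), NA marks questions excluded
as not applicable, and scores of 1–2 require a note (enforced at
validation, listing every offender). Level and overall means **pool
item scores** (mean over all contributing responses in the grain)
rather than averaging site means; pooling makes the level mean equal to
the item-count-weighted mean of site means and avoids giving a
one-question site the same weight as a ten-question one. A
`site_means` flag provides the unweighted alternative. NA responses are
excluded from numerator and denominator everywhere; an empty cell is a
gap on the spider diagram, never a zero (which would read as an
off-scale score). The dimension set is configuration: five classic
dimensions by default with a sixth (data use for decision making)
available. The bundled question bank is illustrative, not a
reproduction of any program's full instrument.

## Sampling

Simple random sampling without replacement per stage, restricted at
each stage to children of the previously selected units; exclusions
carry machine-readable reason codes; backups are drawn in the same
random pass after the primaries so one seed determines both, and
substitute in draw order. The module is a fieldwork-feasibility
snapshot, not a design-based survey: no weights, no variance
estimation.

## The synthetic generator

The generator's structural defaults are one assessment round's worth of
data: 4 districts × 2 facilities × 7 CHWs over a 3-month quarter, which
matches the typical sampled footprint (8 facilities, a few dozen CHWs).
Case arrivals are Poisson per CHW-month per illness (rates 6 / 4 / 3
for malaria / diarrhea / pneumonia — register volumes in the low
hundreds per facility-quarter, the observed order of magnitude); a
Poisson process is the minimal count model and is configurable.

Four error processes, each with its own seed stream:

| knob | default | acts on |
|---|---|---|
| `p_evidence_omission` | malaria 0.05, pneumonia 0.15, diarrhea 0.30 | register entry: evidence fields dropped, treatment kept |
| `p_transcription`, `transcription_sigma` | 0.10, σ = 5 | a report cell: `round(N(0, σ))` added, truncated at 0 |
| `p_report_missing` | community 0.10, facility 0.05, district 0.02, terminals 0 | a whole monthly report |
| `p_field_blank` | 0.02 | a single cell blanked on a present report |

The illness ordering of the omission defaults follows the common field
pattern (diarrhea worst-documented, RDT-anchored malaria best); the
absolute values are illustrative, as no public register dataset
quantifies them. Evidence omission deliberately never changes counts,
so it moves verification ratios while leaving consistency ratios alone;
transcription, loss and blanking do the reverse — the two failure
families the metrics measure separately.

Aggregation semantics: the facility clerk **sums** the CHW forms that
were submitted (skipping blanks); district and terminal clerks **copy**
per-facility rows, carrying blanks forward and producing no row when
the source row never arrived. Report loss at a lower level therefore
propagates as under-reporting above it, the dominant real mechanism.
Submission dates are unrecorded by default (so timeliness reports *not
assessable*, the usual field outcome); a flag turns them on.

Every realized event (lost report, per-cell delta, blanked field,
omitted evidence) is recorded in the ground truth, and
`GroundTruth.replay_reports` re-applies them to the true counts through
the same pipeline, reproducing the emitted reports exactly. With all
probabilities 0 the observed data equal the truth at every level:
ratios 1, differences 0, availability and completeness 100%.

What the generator does **not** emulate: seasonality, CHW behavior
change, stockout-driven treatment suppression, correlated errors
(e.g. one clerk systematically miscopying), illegible-but-present
values, and registers that disagree with themselves. Tests passing on
synthetic data therefore demonstrate that the metrics measure what they
claim under independent, stationary error processes — not that any
particular real system has those error rates.

## Verification problem sizes

The self-checks use: the published 8-facility count table (recomputed
differences compared cell-for-cell); 1,000 random count tables for the
telescoping identity; 20 seeds of the default structure for the
zero-error identity; ~5,000 treated encounters (500 CHW-months at rate
10) for recovering a 20% evidence-omission rate and 10,000 community
site-months for recovering a 20% report-loss rate, both against 99%
exact (Clopper–Pearson-style binomial-quantile) bands; and 10,000 seeds
of a 2-of-4 draw for sampling uniformity. These sizes put Monte-Carlo
noise well inside the acceptance bands while keeping the whole suite
interactive.

## Known limitations

- Tracing assumes higher levels keep per-facility rows; systems that
  only store district totals cannot be traced below that resolution
  (the model would need an allocation rule the data do not contain).
- The availability metric counts months with ≥ 1 report; duplicate
  reports for one site-month are tolerated but not flagged.
- The questionnaire applicability filter is feature-based per level;
  per-site applicability (one facility with electronic entry) is not
  modeled.
- Clinical correctness beyond recorded evidence (dosing, referral
  compliance) is out of scope: the rules verify recording, not care.
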