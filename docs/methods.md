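# Methods

## The score and its assumptions

The completeness score treats documentation quality as multiplicative:
each of ten information categories carries a penalty fraction `P`, and a
combination's score is the product of `(1 − P)` over its absent categories.
Absence in one category therefore scales the score by a fixed factor
regardless of what else is missing, and the score of a fully documented
combination is exactly 1.0 while the all-absent floor is
0.5 · 0.7⁴ · 0.9⁵ = 0.07088… ≈ 0.07. The unit of scoring is the ADR-drug
combination — the Cartesian product of a report's reactions and its
suspect/interacting drugs — and the report's value is the arithmetic mean
over those combinations (its maximum is kept as the "best" score, useful
when a reference assessed only one leading combination per report).

Two categories are binary by the nature of structured line listings.  The
time to onset is computable only when both the drug start date and the
reaction start date are complete, valid `DD/MM/YYYY` strings and their
difference is non-negative (a same-day onset, 0 days, counts as present);
partial dates (`MM/YYYY`, `YYYY`), impossible calendar dates and reversed
orderings all score as absent with the full 50% penalty — no graded
uncertainty tiers exist because the listing carries no uncertainty
information.  Age likewise counts only as an exact numeric value; age-group
labels are not present in the structured export and are not accepted as a
fallback.  Dose counts as present with any numeric token in any unit
("40 mg", "2 tablets"); the comments category is present when any of the
narrative, reporter's-comment or sender's-comment cells is non-absent.
The score deliberately measures only whether structured information is
*present*, never whether free text is informative.

## Input dialect

The exact EudraVigilance column titles and intra-cell separators are not
public, so the reader treats them as configuration: columns are located by
case-insensitive substring keywords (defaults cover titles like "Patient
Age Group/Age"), absence placeholders default to
{"not available", "not specified", "unknown", ""} compared
case-insensitively after trimming, and multi-valued cells (several drugs or
reactions per report) split on a configurable separator, newline within a
cell by default.  Per-drug attribute lists (role, start date, dose,
indication) align positionally with the drug-name list, per-reaction
attributes with the reaction list; a short attribute list is padded with
absent (and logged) rather than dropping a drug, because losing a drug
changes the report mean while losing an attribute only lowers one
combination.  Drug roles map by substring: "interact" → interacting,
"concomitant"/"not suspect" → concomitant, "suspect" → suspect; any other
non-absent value, and an absent role, default to suspect so the combination
is scored rather than silently dropped.  Duplicate report identifiers are
fatal (per-report aggregation would be ill-defined); the check runs during
combination expansion because the raw reader is dialect-agnostic and does
not yet know which column holds the identifier.

Processing order is fixed: read → resolve columns → expand combinations →
remove vaccine/hyposensitisation reports (report-level, by drug-name
substring against a configurable term list) → drop concomitant combinations
→ score → aggregate → summarise.

## Numerical choices

Scores are carried at full precision; display columns and the per-report
distinct-value count use 2-decimal rounding, matching the score's natural
reporting precision and preventing floating-point noise from manufacturing
distinctness.  The report mean sums scores in sorted order so it is exactly
invariant under permutation of the input rows.  The well-documented
threshold (mean ≥ 0.8) and the deviation threshold (|difference| ≥ 0.3) are
inclusive.  Dataset SD uses the n−1 denominator (0.0 for a single report);
the IQR is the 25th–75th percentile with linear interpolation.

## Validation

Agreement with a reference score set (e.g. the same reports scored in
another database) is quantified with the intraclass correlation for
two-way random effects, absolute agreement, single measurement — ICC(2,1),
the natural model for the same reports rated by two systems; ICC(3,1)
(consistency) is selectable for sensitivity analysis.  The estimate and its
95% CI are computed directly from the two-way ANOVA mean squares with the
standard F-distribution bounds (McGraw & Wong), because the installed
pingouin rounds the interval to two decimals; pingouin serves as an
independent cross-check in the tests.  Fewer than three pairs, or zero
variance in both columns, yield an explicit degenerate result instead of a
number.  Flagged deviations are attributed at exactly one level: any
disagreement in the report-level categories (sex, age, country, primary
reporter, report type, comments) attributes the report there; only
otherwise are its combinations compared (aligned on drug and reaction) in
the combination-level categories (time to onset, indication, outcome,
dose).  Categories the reference cannot carry — typically comments, when
the reference listing has no free-text fields — can be masked out of
attribution.

## Synthetic data

The generator emits structurally faithful listings: placeholder strings,
newline-separated multi-value cells, DD/MM/YYYY dates with a configurable
fraction emitted in partial format, vaccine-name drugs in a configurable
fraction of reports, and per-category missingness probabilities.  Ground
truth (per-combination presence and score, per-report mean/best) is
computed by an inline product with its own penalty constants, independent
of the scoring module, so pipeline recovery is a genuine two-route check.
Default conditions were chosen once as a realistic spontaneous-report
profile — demographics mostly present (sex 5%, country 2%, report type 1%
absent), age 20%, outcome 30%, indication and dose 40%, narrative and time
to onset 50% absent; 1–5 drugs and reactions per report skewed towards 1;
75/5/20% suspect/interacting/concomitant roles; 5% vaccine reports; 10%
partial dates — which yields mean report scores around 0.45–0.6, the band
typical of spontaneous-report datasets.  Drug names come from an invented
lexicon (no real products).  Dates are constructed so every computable time
to onset is non-negative: drug starts fall within 5 days of a per-report
base date and reaction onsets 6–36 days after it; TTO absence is driven
entirely by absent or partial date emission, with each of the two dates
dropped at probability 1 − √(1 − p_tto) so a pair's TTO-present probability
is 1 − p_tto.  All draws come from a single seeded NumPy generator in a
fixed order, so identical config + seed give byte-identical files.

What the generator does not emulate: real-world vocabulary drift in column
titles, mixed or inconsistent separators, free-text quality, correlations
between categories (e.g. physician reports being more complete), or the
score distributions of any particular real dataset.  Passing the recovery
tests therefore demonstrates that the pipeline computes the score exactly
as specified on dialect-conformant input, not that any particular real
export will parse without configuration.

Reference perturbation flips category presence in a copy of the ground
truth — per report for report-level categories, per combination for
combination-level ones — recording every flip, so attribution tests can
require that 100% of attributable flagged reports name exactly the planted
category.

## Problem sizes

Tests run the pipeline on seeded listings of up to 1,000 reports (about
3,000 combinations), enough for exact recovery checks and for empirical
missingness to resolve within three binomial standard deviations; the
acceptance script's anchor values are single-report computations.

## Known limitations

Only the documented csv/xlsx dialect is supported — not E2B/ICSR XML, not
the public-access aggregated listing format.  Scoring of vaccine reports is
possible (`keep_vaccines`) but the score's behaviour on vaccines is
unvalidated, which is why they are excluded by default.  The report-type
category is scored strictly as present/absent; non-spontaneous values are
only warned about.  Reference score sets must share report identifiers with
the scored listing; cross-database identifier matching is out of scope.
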