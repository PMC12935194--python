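# vigiscore

Completeness scoring for pharmacovigilance line listings.

Spontaneous adverse-drug-reaction (ADR) reports vary enormously in how much
structured information they carry, and assessors triaging thousands of
reports need a reproducible way to find the well-documented ones.
`vigiscore` implements a vigiGrade-style multiplicative completeness score
adapted to the structured line listings exported from EudraVigilance (one
row per report, one column per information category, placeholder strings
for absent values), for pharmacovigilance researchers, competent
authorities and marketing-authorisation holders with access to such
exports.

## The score

For each ADR-drug combination *(reaction, drug)* of a report, ten
information categories are checked and the score is the product

```
score = ∏ᵢ₌₁¹⁰ (1 − Pᵢ · [category i absent])
```

with penalties Pᵢ:

| category | penalty | presence rule |
|---|---|---|
| time to onset | 50% | computable as ≥ 0 days from complete DD/MM/YYYY drug start and reaction start dates |
| indication | 30% | non-placeholder |
| outcome | 30% | non-placeholder |
| sex | 30% | non-placeholder |
| age | 30% | numeric age value (an age-group label does not count) |
| dose | 10% | contains a numeric token, any unit |
| country | 10% | non-placeholder |
| primary reporter | 10% | non-placeholder |
| report type | 10% | non-placeholder |
| comments / narrative | 10% | any of narrative, reporter's or sender's comment |

The score ranges from 0.07 (all ten absent; exactly 0.5·0.7⁴·0.9⁵ = 0.0709)
to 1.0. In line listings, time to onset and age are inherently binary —
present exactly or absent — so the graded "lenient" penalty tiers of the
original vigiGrade do not apply. A report's value is the mean over its
suspect and interacting (never concomitant) drug combinations; reports with
a mean ≥ 0.8 count as well-documented. Reports referring to vaccines or
hyposensitisation solutions are removed before scoring.

The package also ships a seeded synthetic line-listing generator with exact
ground truth (real exports cannot be redistributed) and a validation module:
per-report differences against a reference score set, intraclass
correlation ICC(2,1) with a 95% CI, ±0.3 deviation flagging, and
category-level attribution of flagged deviations at report level and, where
the report level is concordant, at ADR-drug level.

## Worked example

```
$ python examples/score_a_line_listing.py
reports scored:        172
vaccine reports removed: 9
mean (SD):             0.46 (0.18)
median [IQR]:          0.42 [0.32 - 0.57]
range:                 0.15 - 1.00
well-documented (>=0.8): 10 (5.8%)
distinct-value histogram: {'1': 80, '2': 54, '3': 17, '4': 14, '>=5': 7}
```

The script generates a 200-report synthetic listing, removes the 9 vaccine
reports and the reports with only concomitant drugs, and scores the rest.
The mean of 0.46 says the typical report documents roughly half of the
weighted information; 10 reports clear the well-documented threshold; 80
reports have a single score value across all their ADR-drug combinations.

The same pipeline is available from the shell:

```
vigiscore simulate --out-dir data --seed 1 --n-reports 200
vigiscore score data/synthetic_linelisting.csv --out-dir results
vigiscore compare --scores results/report_scores.csv --reference ref.csv --out-dir results
```

`score` writes one file per ADR-drug combination (ten presence flags plus
the score), one per report (mean, best, combination count, distinct-value
count, well-documented flag) and a dataset summary. Column keywords,
placeholder strings, penalties and vaccine terms are configurable via
`--config config.yaml`.

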