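"""Score a single ADR-drug combination and show how each absence penalises.

Starts from a fully documented record (score 1.0) and knocks out one
category at a time, printing the resulting score — the multiplicative
structure means each absence scales the score by a fixed factor.
"""

import datetime

from vigiscore import CombinationRecord, assess_presence, score_combination

full = CombinationRecord(
    report_id="CASE-1",
    drug_name="Alphatensin",
    reaction_term="Nausea",
    drug_start_date=datetime.date(2020, 1, 1),
    reaction_start_date=datetime.date(2020, 1, 5),
    dose_text="40 mg",
    indication_text="Hypertension",
    outcome_text="Recovered/Resolved",
    sex="Female",
    age_text="34 Year(s)",
    country="DE",
    reporter_qualification="Physician",
    report_type="Spontaneous",
    narrative_present=True,
)
print(f"fully documented: {score_combination(assess_presence(full)):.2f}")

knockouts = {
    "time to onset (no drug start date)": dict(drug_start_date=None),
    "indication": dict(indication_text=None),
    "outcome": dict(outcome_text=None),
    "sex": dict(sex=None),
    "age (group label only)": dict(age_text="Adult"),
    "dose (no numeric token)": dict(dose_text="some tablets"),
    "country": dict(country=None),
    "primary reporter": dict(reporter_qualification=None),
    "report type": dict(report_type=None),
    "comments/narrative": dict(narrative_present=False),
}
for label, override in knockouts.items():
    rec = CombinationRecord(**{**full.__dict__, **override})
    print(f"missing {label:<35s} -> {score_combination(assess_presence(rec)):.2f}")

# 0.50 for a missing time to onset, 0.70 for the 30% categories and 0.90 for
# the 10% categories; all ten missing together would give 0.07.
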