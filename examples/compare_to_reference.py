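"""Validate scores against a reference set with a known, planted difference.

Generates a synthetic listing, scores it, then builds a reference score set
in which the age category has been flipped in every report.  The comparison
flags the reports whose score shifted by at least 0.3 and the attribution
step recovers "age" as the cause in every attributable case.
"""

import numpy as np

from vigiscore import (
    SyntheticConfig,
    attribute_discrepancies,
    compare_scores,
    generate_linelisting,
    perturb_reference,
    presence_frame,
    score_line_listing,
)
from vigiscore.scoring import CATEGORIES

cfg = SyntheticConfig(n_reports=300, seed=7, vaccine_fraction=0.0)
listing, truth = generate_linelisting(cfg)
result = score_line_listing(listing)

reference_truth = perturb_reference(truth, {"age": 1.0}, seed=11)
reference = {
    row.report_id: row.true_mean
    for row in reference_truth.reports.itertuples()
    if np.isfinite(row.true_mean)
}

cmp = compare_scores(result.report_scores, reference, threshold=0.3)
icc = cmp.icc
print(f"pairs compared:   {len(cmp.pairs)}")
print(f"mean difference:  {cmp.mean_difference:+.3f} (SD {cmp.sd_difference:.3f})")
print(f"ICC(2,1):         {icc.estimate:.3f} [{icc.ci_lower:.3f}, {icc.ci_upper:.3f}]")
print(f"flagged at |d|>=0.3: {len(cmp.flagged)}")

cols = ["report_id", "drug_name", "reaction_term"] + list(CATEGORIES)
attr = attribute_discrepancies(
    list(cmp.flagged.report_id),
    presence_frame(result.combination_scores),
    reference_truth.combinations[reference_truth.combinations.scoreable][cols],
)
print(f"report-level attributions: {attr.n_report_level}")
print(f"category counts:  { {k: v for k, v in attr.report_level_counts.items() if v} }")

# Every flagged report is attributed to 'age' at report level: the planted
# flip is exactly what the deviation attribution recovers.
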