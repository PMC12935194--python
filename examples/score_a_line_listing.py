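"""Score a line listing end to end and print the dataset summary.

Builds a small synthetic listing (stand-in for an EudraVigilance export),
scores every ADR-drug combination with the multiplicative penalty scheme,
aggregates per report, and prints the distribution statistics.
"""

from pathlib import Path

from vigiscore import (
    SyntheticConfig,
    generate_linelisting,
    score_line_listing,
    write_line_listing,
)

out = Path("scratch_example")
out.mkdir(exist_ok=True)
listing, _ = generate_linelisting(SyntheticConfig(n_reports=200, seed=1))
path = write_line_listing(listing, out / "listing.csv")

result = score_line_listing(path)
s = result.summary
print(f"reports scored:        {s.n_reports}")
print(f"vaccine reports removed: {len(result.excluded_vaccine_reports)}")
print(f"mean (SD):             {s.mean:.2f} ({s.sd:.2f})")
print(f"median [IQR]:          {s.median:.2f} [{s.q1:.2f} - {s.q3:.2f}]")
print(f"range:                 {s.minimum:.2f} - {s.maximum:.2f}")
print(f"well-documented (>=0.8): {s.n_well_documented} ({s.pct_well_documented:.1f}%)")
print(f"distinct-value histogram: {dict(s.distinct_value_histogram)}")

# A mean near 0.5 is typical of spontaneous reports: structured demographics
# are usually present, while dates, doses and free text often are not.
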