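"""End-to-end scoring pipeline and tabular export helpers.

Fixed processing order: read → resolve columns → expand to ADR-drug
combinations → remove vaccine/hyposensitisation reports → drop concomitant
combinations → score → aggregate per report → summarise.  Export frames
carry both a 2-decimal display column and the exact value, so downstream
averaging never accumulates rounding error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .linelist import RawLineListing, expand_combinations, read_line_listing, resolve_columns
from .scoring import (
    CATEGORIES,
    CombinationScore,
    DatasetSummary,
    PenaltyScheme,
    ReportScore,
    exclude_vaccines,
    score_dataset,
    summarize_dataset,
)

logger = logging.getLogger("vigiscore")


@dataclass
class ScoredDataset:
    """Everything the pipeline produces for one line listing."""

    combination_scores: list[CombinationScore]
    report_scores: list[ReportScore]
    summary: DatasetSummary
    excluded_vaccine_reports: list[str]
    excluded_other_reports: list[str]  # unparseable or concomitant-only


def score_line_listing(
    source: str | Path | RawLineListing,
    config: PipelineConfig | None = None,
    input_format: str = "auto",
    keep_vaccines: bool = False,
) -> ScoredDataset:
    """Score a line listing from a path or an in-memory listing."""
    config = config or PipelineConfig()
    if isinstance(source, RawLineListing):
        listing = source
    else:
        listing = read_line_listing(source, format=input_format, dialect=config.dialect)
    cmap = resolve_columns(listing, config.keywords)
    records = expand_combinations(
        listing, cmap, dialect=config.dialect, placeholders=config.placeholders
    )
    all_ids = {r.report_id for r in records}
    if keep_vaccines:
        kept = records
    else:
        kept = exclude_vaccines(records, config.vaccine_terms)
    vaccine_ids = sorted(all_ids - {r.report_id for r in kept})

    scheme = PenaltyScheme.from_mapping(config.penalties)
    combo_scores, report_scores = score_dataset(kept, scheme)
    if not report_scores:
        raise ValidationError("no scoreable reports remain after exclusions")
    scored_ids = {r.report_id for r in report_scores}
    other_excluded = sorted(all_ids - set(vaccine_ids) - scored_ids)
    return ScoredDataset(
        combination_scores=combo_scores,
        report_scores=report_scores,
        summary=summarize_dataset(report_scores),
        excluded_vaccine_reports=vaccine_ids,
        excluded_other_reports=other_excluded,
    )


def combination_frame(combos: list[CombinationScore]) -> pd.DataFrame:
    """One row per ADR-drug combination: presence flags plus the score."""
    return pd.DataFrame(
        [
            {
                "report_id": c.report_id,
                "drug_name": c.drug_name,
                "reaction_term": c.reaction_term,
                "drug_role": c.drug_role,
                **c.presence.as_dict(),
                "score_display": f"{c.score:.2f}",
                "score_exact": c.score,
            }
            for c in combos
        ],
        columns=["report_id", "drug_name", "reaction_term", "drug_role",
                 *CATEGORIES, "score_display", "score_exact"],
    )


def report_frame(reports: list[ReportScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "report_id": r.report_id,
                "mean_display": f"{r.mean_score:.2f}",
                "mean_exact": r.mean_score,
                "best_display": f"{r.best_score:.2f}",
                "best_exact": r.best_score,
                "n_combinations": r.n_combinations,
                "n_distinct_scores": r.n_distinct_scores,
                "well_documented": r.well_documented,
            }
            for r in reports
        ]
    )


def summary_frame(summary: DatasetSummary) -> pd.DataFrame:
    """The dataset summary as (metric, value) rows."""
    rows = [
        ("n_reports", summary.n_reports),
        ("mean", round(summary.mean, 4)),
        ("sd", round(summary.sd, 4)),
        ("median", round(summary.median, 4)),
        ("q1", round(summary.q1, 4)),
        ("q3", round(summary.q3, 4)),
        ("min", round(summary.minimum, 4)),
        ("max", round(summary.maximum, 4)),
        ("n_well_documented", summary.n_well_documented),
        ("pct_well_documented", round(summary.pct_well_documented, 1)),
    ]
    rows += [
        (f"n_reports_with_{k}_distinct_values".replace(">=", "ge"), v)
        for k, v in summary.distinct_value_histogram.items()
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])
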