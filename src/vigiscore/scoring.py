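"""The multiplicative completeness score for ADR-drug combinations.

Ten information categories are checked per (reaction, drug) pair.  The score
starts at 1.0 and is multiplied by ``1 - penalty`` for every category whose
information is absent:

    score = prod_i (1 - P_i * [category i absent])

With the default penalties (time to onset 50%; indication, outcome, sex and
age 30% each; dose, country, primary reporter, report type and comments 10%
each) the score ranges from 0.5 * 0.7^4 * 0.9^5 = 0.0709 (nothing present)
to 1.0 (everything present).  Two categories are binary by construction in
EudraVigilance line listings: the time to onset is either computable exactly
from complete DD/MM/YYYY start dates (drug and reaction, difference >= 0
days) or counted absent, and age counts only as an exact numeric value —
there is no age-group tier.

Per report, the score is the arithmetic mean over its suspect and
interacting (never concomitant) drug combinations; a report with a mean of
at least 0.8 is considered well-documented.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .linelist import CombinationRecord

logger = logging.getLogger("vigiscore")

#: The ten scored categories, in canonical order.
CATEGORIES: tuple[str, ...] = (
    "time_to_onset",
    "indication",
    "outcome",
    "sex",
    "age",
    "dose",
    "country",
    "primary_reporter",
    "report_type",
    "comments",
)

DEFAULT_PENALTIES: dict[str, float] = {
    "time_to_onset": 0.50,
    "indication": 0.30,
    "outcome": 0.30,
    "sex": 0.30,
    "age": 0.30,
    "dose": 0.10,
    "country": 0.10,
    "primary_reporter": 0.10,
    "report_type": 0.10,
    "comments": 0.10,
}

#: Scores are displayed, and counted as distinct, at this rounding.
DISPLAY_DECIMALS = 2

WELL_DOCUMENTED_THRESHOLD = 0.8  # inclusive


@dataclass(frozen=True)
class PenaltyScheme:
    """Penalty fraction per category; multiplicative on absence."""

    penalties: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.penalties)
        if keys != set(CATEGORIES):
            raise ValidationError(
                f"penalty scheme must define exactly the ten categories; "
                f"missing={sorted(set(CATEGORIES) - keys)}, "
                f"unexpected={sorted(keys - set(CATEGORIES))}"
            )
        bad = {k: v for k, v in self.penalties.items() if not (0.0 < v < 1.0)}
        if bad:
            raise ValidationError(f"penalty fractions must lie in (0, 1): {bad}")

    @classmethod
    def default(cls) -> "PenaltyScheme":
        return cls(penalties=dict(DEFAULT_PENALTIES))

    @classmethod
    def from_mapping(cls, overrides: Mapping[str, float] | None) -> "PenaltyScheme":
        if not overrides:
            return cls.default()
        merged = dict(DEFAULT_PENALTIES)
        unknown = sorted(set(overrides) - set(CATEGORIES))
        if unknown:
            raise ValidationError(f"unknown penalty categories: {unknown}")
        merged.update(overrides)
        return cls(penalties=merged)

    def floor(self) -> float:
        """The all-absent score, 0.0709 with the default penalties."""
        return math.prod(1.0 - p for p in self.penalties.values())


@dataclass(frozen=True)
class CategoryPresence:
    """One boolean per scored category; True = information present."""

    time_to_onset: bool
    indication: bool
    outcome: bool
    sex: bool
    age: bool
    dose: bool
    country: bool
    primary_reporter: bool
    report_type: bool
    comments: bool

    def as_dict(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in CATEGORIES}

    def absent_categories(self) -> tuple[str, ...]:
        return tuple(c for c in CATEGORIES if not getattr(self, c))

    @classmethod
    def all_present(cls) -> "CategoryPresence":
        return cls(**{c: True for c in CATEGORIES})

    @classmethod
    def all_absent(cls) -> "CategoryPresence":
        return cls(**{c: False for c in CATEGORIES})


@dataclass(frozen=True)
class CombinationScore:
    """Score and presence pattern of one ADR-drug combination."""

    report_id: str
    drug_name: str
    reaction_term: str
    drug_role: str
    presence: CategoryPresence
    score: float


@dataclass(frozen=True)
class ReportScore:
    """Per-report aggregate over its suspect/interacting combinations."""

    report_id: str
    mean_score: float
    best_score: float
    n_combinations: int
    n_distinct_scores: int
    well_documented: bool


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset-level distribution statistics of report mean scores."""

    n_reports: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    n_well_documented: int
    pct_well_documented: float
    distinct_value_histogram: Mapping[str, int]  # bins "1", "2", "3", "4", ">=5"


def compute_time_to_onset(
    drug_start: datetime.date | None, reaction_start: datetime.date | None
) -> int | None:
    """Days from drug start to reaction start, or None when not computable.

    Requires both dates and a non-negative difference; a same-day onset
    (0 days) counts as available.
    """
    if drug_start is None or reaction_start is None:
        return None
    delta = (reaction_start - drug_start).days
    return delta if delta >= 0 else None


def _has_digit(text: str | None) -> bool:
    return text is not None and any(ch.isdigit() for ch in text)


def assess_presence(rec: CombinationRecord) -> CategoryPresence:
    """Decide, per category, whether the combination carries the information.

    Dose counts as present only with a numeric token (any unit); age only as
    a numeric value (an age-group label alone does not count); time to onset
    only when computable as >= 0 days from complete dates.
    """
    return CategoryPresence(
        time_to_onset=compute_time_to_onset(rec.drug_start_date, rec.reaction_start_date)
        is not None,
        indication=rec.indication_text is not None,
        outcome=rec.outcome_text is not None,
        sex=rec.sex is not None,
        age=_has_digit(rec.age_text),
        dose=_has_digit(rec.dose_text),
        country=rec.country is not None,
        primary_reporter=rec.reporter_qualification is not None,
        report_type=rec.report_type is not None,
        comments=rec.narrative_present,
    )


def score_combination(
    presence: CategoryPresence, scheme: PenaltyScheme | None = None
) -> float:
    """Multiply 1.0 by (1 - penalty) for every absent category."""
    scheme = scheme or PenaltyScheme.default()
    score = 1.0
    for cat in CATEGORIES:
        if not getattr(presence, cat):
            score *= 1.0 - scheme.penalties[cat]
    return score


def score_report(combos: Sequence[CombinationScore]) -> ReportScore:
    """Aggregate one report's combination scores to mean/best.

    Distinct values are counted at 2-decimal rounding so floating-point
    noise cannot manufacture distinctness.
    """
    if not combos:
        raise ValidationError("cannot score a report with no combinations")
    ids = {c.report_id for c in combos}
    if len(ids) != 1:
        raise ValidationError(f"combinations from multiple reports passed together: {sorted(ids)}")
    scores = [c.score for c in combos]
    # summing in sorted order makes the mean exactly invariant under
    # permutation of the input combinations
    mean = float(np.sort(scores).sum() / len(scores))
    return ReportScore(
        report_id=combos[0].report_id,
        mean_score=mean,
        best_score=float(max(scores)),
        n_combinations=len(combos),
        n_distinct_scores=len({round(s, DISPLAY_DECIMALS) for s in scores}),
        well_documented=mean >= WELL_DOCUMENTED_THRESHOLD,
    )


def exclude_vaccines(
    records: Iterable[CombinationRecord], term_list: Sequence[str]
) -> list[CombinationRecord]:
    """Drop every combination of any report containing a vaccine-term drug.

    Removal is report-level: one matching drug removes the whole report,
    since scoring targets drugs, not vaccines or hyposensitisation solutions.
    """
    records = list(records)
    terms = [t.lower() for t in term_list]
    if not terms:
        return records
    flagged = {
        r.report_id
        for r in records
        if any(t in r.drug_name.lower() for t in terms)
    }
    if flagged:
        logger.info(
            "%d report(s) removed as vaccine/hyposensitisation: %s",
            len(flagged), ", ".join(sorted(flagged)),
        )
    return [r for r in records if r.report_id not in flagged]


def score_dataset(
    records: Iterable[CombinationRecord],
    scheme: PenaltyScheme | None = None,
) -> tuple[list[CombinationScore], list[ReportScore]]:
    """Score every suspect/interacting combination and aggregate per report.

    Concomitant-drug combinations are excluded from scoring; a report whose
    drugs are all concomitant is excluded with a warning.  Output is ordered
    by report_id, then input order within a report.
    """
    scheme = scheme or PenaltyScheme.default()
    records = list(records)

    odd_types = sorted(
        {
            r.report_type
            for r in records
            if r.report_type is not None and "spontaneous" not in r.report_type.lower()
        }
    )
    if odd_types:
        logger.warning("non-spontaneous report types present: %s", ", ".join(odd_types))

    by_report: dict[str, list[CombinationScore]] = {}
    order: dict[str, int] = {}
    dropped_all_concomitant: set[str] = set()
    for idx, rec in enumerate(records):
        order.setdefault(rec.report_id, idx)
        by_report.setdefault(rec.report_id, [])
        if rec.drug_role == "concomitant":
            continue
        presence = assess_presence(rec)
        by_report[rec.report_id].append(
            CombinationScore(
                report_id=rec.report_id,
                drug_name=rec.drug_name,
                reaction_term=rec.reaction_term,
                drug_role=rec.drug_role,
                presence=presence,
                score=score_combination(presence, scheme),
            )
        )

    combo_scores: list[CombinationScore] = []
    report_scores: list[ReportScore] = []
    for rid in sorted(by_report):
        combos = by_report[rid]
        if not combos:
            dropped_all_concomitant.add(rid)
            continue
        combo_scores.extend(combos)
        report_scores.append(score_report(combos))
    if dropped_all_concomitant:
        logger.warning(
            "%d report(s) excluded: only concomitant drugs (%s)",
            len(dropped_all_concomitant), ", ".join(sorted(dropped_all_concomitant)),
        )
    return combo_scores, report_scores


def summarize_dataset(reports: Sequence[ReportScore]) -> DatasetSummary:
    """Distribution statistics of the per-report mean scores.

    SD uses the n-1 denominator (0.0 for a single report); the distinct-value
    histogram bins reports by how many different combination scores they
    contain: 1 (or all equal), 2, 3, 4, >=5.
    """
    if not reports:
        raise ValidationError("cannot summarize an empty set of report scores")
    means = np.array([r.mean_score for r in reports], dtype=float)
    n = len(means)
    hist = {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
    for r in reports:
        key = str(r.n_distinct_scores) if r.n_distinct_scores < 5 else ">=5"
        hist[key] += 1
    n_well = sum(r.well_documented for r in reports)
    return DatasetSummary(
        n_reports=n,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)) if n > 1 else 0.0,
        median=float(np.median(means)),
        q1=float(np.percentile(means, 25)),
        q3=float(np.percentile(means, 75)),
        minimum=float(means.min()),
        maximum=float(means.max()),
        n_well_documented=int(n_well),
        pct_well_documented=100.0 * n_well / n,
        distinct_value_histogram=hist,
    )
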