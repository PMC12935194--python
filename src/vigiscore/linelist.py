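"""Reading, writing and expanding EudraVigilance-style line listings.

A line listing is a flat table with one row per ADR report and one column per
information category.  Several drugs (and their per-drug attributes) or
several reactions (and their per-reaction attributes) are packed into single
cells, separated by a dialect-configurable separator (newline by default).
Absent values are encoded as placeholder strings such as ``"Not available"``.

The module reads csv and xlsx into a :class:`RawLineListing` with every cell
kept as a raw string, resolves columns by case-insensitive keyword matching,
and expands each report into one :class:`CombinationRecord` per
(reaction, drug) pair — the unit at which the completeness score is computed.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import (
    DEFAULT_KEYWORDS,
    DEFAULT_PLACEHOLDERS,
    REQUIRED_FIELDS,
    SEMANTIC_FIELDS,
    Dialect,
)
from .errors import InputError, ValidationError

logger = logging.getLogger("vigiscore")

_DATE_RE = re.compile(r"^(\d{2})/(\d{2})/(\d{4})$")


@dataclass
class RawLineListing:
    """A line listing as read from disk: all cells are raw strings."""

    frame: pd.DataFrame
    source_format: str = "csv"

    def __post_init__(self) -> None:
        if self.frame.shape[1] == 0:
            raise ValidationError("line listing has no columns")
        dupes = [c for c in self.frame.columns if list(self.frame.columns).count(c) > 1]
        if dupes:
            raise ValidationError(f"duplicate column labels in line listing: {sorted(set(dupes))}")

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawLineListing):
            return NotImplemented
        return self.columns == other.columns and self.frame.reset_index(drop=True).equals(
            other.frame.reset_index(drop=True)
        )


@dataclass(frozen=True)
class ColumnMap:
    """Resolved semantic field -> column label (None when unmapped)."""

    mapping: Mapping[str, str | None]

    def column(self, fld: str) -> str | None:
        return self.mapping.get(fld)

    def require(self, fld: str) -> str:
        col = self.mapping.get(fld)
        if col is None:
            raise ValidationError(f"required field {fld!r} is not mapped to any column")
        return col


@dataclass(frozen=True)
class CombinationRecord:
    """One (reaction, drug) pair of one report, placeholder-normalized.

    Optional fields are ``None`` when the source cell held a placeholder;
    ``narrative_present`` is true when at least one of the narrative,
    reporter's-comment or sender's-comment cells was non-absent.
    """

    report_id: str
    drug_name: str
    reaction_term: str
    drug_role: str = "suspect"  # suspect | interacting | concomitant
    drug_start_date: datetime.date | None = None
    dose_text: str | None = None
    indication_text: str | None = None
    reaction_start_date: datetime.date | None = None
    outcome_text: str | None = None
    sex: str | None = None
    age_text: str | None = None
    country: str | None = None
    reporter_qualification: str | None = None
    report_type: str | None = None
    narrative_present: bool = False


def read_line_listing(
    path: str | Path,
    format: str = "auto",
    dialect: Dialect | None = None,
) -> RawLineListing:
    """Read a csv or xlsx line listing, keeping every cell as a raw string.

    ``format="auto"`` infers from the file extension.  The file must have a
    header row; an empty or header-only file is a validation error.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    if not path.exists():
        raise InputError(f"line listing not found: {path}")
    if format == "auto":
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    if format not in ("csv", "xlsx"):
        raise InputError(f"unsupported line-listing format: {format!r}")
    try:
        if format == "csv":
            frame = pd.read_csv(
                path, dtype=str, keep_default_na=False, sep=dialect.delimiter
            )
        else:
            frame = pd.read_excel(
                path, dtype=str, keep_default_na=False, sheet_name=dialect.sheet
            )
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"line listing is empty: {path}") from exc
    except (OSError, ValueError) as exc:
        raise InputError(f"could not read line listing {path}: {exc}") from exc
    frame.columns = [str(c) for c in frame.columns]
    if len(frame) == 0:
        raise ValidationError(f"line listing has a header but no data rows: {path}")
    return RawLineListing(frame=frame, source_format=format)


def write_line_listing(
    listing: RawLineListing,
    path: str | Path,
    format: str = "auto",
    dialect: Dialect | None = None,
) -> Path:
    """Write a listing back to csv or xlsx, cell-for-cell."""
    path = Path(path)
    dialect = dialect or Dialect()
    if format == "auto":
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    if format == "csv":
        listing.frame.to_csv(path, index=False, sep=dialect.delimiter, lineterminator="\n")
    elif format == "xlsx":
        listing.frame.to_excel(path, index=False)
    else:
        raise InputError(f"unsupported line-listing format: {format!r}")
    return path


def resolve_columns(
    listing: RawLineListing,
    keyword_config: Mapping[str, Sequence[str]] | None = None,
) -> ColumnMap:
    """Map semantic fields to column labels by case-insensitive substring.

    Each field takes the first column whose label contains any of its
    keywords.  A required field with no match, or one column claimed by two
    fields, is fatal.
    """
    keywords = dict(DEFAULT_KEYWORDS)
    if keyword_config:
        keywords.update({k: tuple(v) for k, v in keyword_config.items()})
    if not keywords:
        raise ValidationError("keyword configuration is empty")

    labels = listing.columns
    lowered = [lab.lower() for lab in labels]
    mapping: dict[str, str | None] = {}
    for fld in SEMANTIC_FIELDS:
        words = keywords.get(fld, ())
        hit: str | None = None
        for lab, low in zip(labels, lowered):
            if any(w.lower() in low for w in words):
                hit = lab
                break
        mapping[fld] = hit

    missing = sorted(f for f in REQUIRED_FIELDS if mapping[f] is None)
    if missing:
        raise ValidationError(
            f"required fields {missing} matched no column; available labels: {labels}"
        )
    claimed: dict[str, str] = {}
    for fld, col in mapping.items():
        if col is None:
            continue
        if col in claimed:
            raise ValidationError(
                f"column {col!r} matched by both {claimed[col]!r} and {fld!r}; "
                "refine the keyword configuration"
            )
        claimed[col] = fld
    unmapped = sorted(f for f, c in mapping.items() if c is None)
    if unmapped:
        logger.info("optional fields without a matching column: %s", ", ".join(unmapped))
    return ColumnMap(mapping=mapping)


def normalize_missing(
    raw: str | None, placeholders: Sequence[str] = DEFAULT_PLACEHOLDERS
) -> str | None:
    """Return ``None`` for placeholder cells, otherwise the trimmed string."""
    if raw is None:
        return None
    trimmed = str(raw).strip()
    lowered = trimmed.lower()
    if any(lowered == p.strip().lower() for p in placeholders):
        return None
    return trimmed if trimmed else None


def parse_date(raw: str | None) -> datetime.date | None:
    """Parse a complete, valid DD/MM/YYYY string; anything else is absent.

    Partial dates (MM/YYYY, YYYY) and impossible calendar dates return
    ``None`` — completeness requires the full, valid day-precision format.
    """
    if raw is None:
        return None
    m = _DATE_RE.match(str(raw).strip())
    if not m:
        logger.debug("date %r rejected: not DD/MM/YYYY", raw)
        return None
    day, month, year = (int(g) for g in m.groups())
    try:
        return datetime.date(year, month, day)
    except ValueError:
        logger.debug("date %r rejected: not a real calendar date", raw)
        return None


def parse_drug_role(raw: str | None) -> str:
    """Map a free-form role string to suspect/interacting/concomitant.

    Unknown non-absent values default to suspect (so they are scored) with a
    warning; absent roles default to suspect silently.
    """
    if raw is None:
        return "suspect"
    low = raw.lower()
    if "interact" in low:
        return "interacting"
    if "concomitant" in low or "not suspect" in low:
        return "concomitant"
    if "suspect" in low:
        return "suspect"
    logger.warning("unrecognised drug role %r: treating as suspect", raw)
    return "suspect"


def split_multi(cell: str | None, separator: str) -> list[str]:
    """Split a multi-valued cell into raw tokens (no normalization)."""
    if cell is None:
        return []
    return str(cell).split(separator)


def _aligned(tokens: list[str], n: int, what: str, report_id: str) -> list[str | None]:
    """Pad/flag an attribute list to align positionally with its value list."""
    if len(tokens) < n:
        if tokens and any(t.strip() for t in tokens):
            logger.warning(
                "report %s: %s list has %d entries for %d values; padding with absent",
                report_id, what, len(tokens), n,
            )
        return list(tokens) + [None] * (n - len(tokens))
    if len(tokens) > n:
        logger.warning(
            "report %s: %s list has %d entries for %d values; extra entries ignored",
            report_id, what, len(tokens), n,
        )
    return list(tokens[:n])


def expand_combinations(
    listing: RawLineListing,
    cmap: ColumnMap,
    dialect: Dialect | None = None,
    placeholders: Sequence[str] = DEFAULT_PLACEHOLDERS,
) -> list[CombinationRecord]:
    """Expand each report row into the Cartesian product of drugs × reactions.

    Per-drug attribute lists (role, start date, dose, indication) align
    positionally with the drug-name list; per-reaction attributes (start
    date, outcome) with the reaction-term list.  Length mismatches are padded
    with absent.  Reports with zero parseable drugs or reactions are skipped
    with a warning; duplicate report identifiers are fatal.
    """
    dialect = dialect or Dialect()
    sep = dialect.separator

    def cell(row: pd.Series, fld: str) -> str | None:
        col = cmap.column(fld)
        if col is None:
            return None
        return str(row[col])

    ids_seen: dict[str, int] = {}
    records: list[CombinationRecord] = []
    for _, row in listing.frame.iterrows():
        report_id = normalize_missing(cell(row, "report_id"), placeholders)
        if report_id is None:
            logger.warning("row with absent report identifier skipped")
            continue
        ids_seen[report_id] = ids_seen.get(report_id, 0) + 1

        drug_tokens = split_multi(cell(row, "drug_names"), sep)
        drugs = [(i, normalize_missing(t, placeholders)) for i, t in enumerate(drug_tokens)]
        drugs = [(i, d) for i, d in drugs if d is not None]
        reaction_tokens = split_multi(cell(row, "reaction_terms"), sep)
        reactions = [
            (j, normalize_missing(t, placeholders)) for j, t in enumerate(reaction_tokens)
        ]
        reactions = [(j, r) for j, r in reactions if r is not None]
        if not drugs or not reactions:
            logger.warning(
                "report %s skipped: no parseable %s",
                report_id, "drugs" if not drugs else "reactions",
            )
            continue

        n_d, n_r = len(drug_tokens), len(reaction_tokens)
        roles = _aligned(split_multi(cell(row, "drug_roles"), sep), n_d, "drug role", report_id)
        d_dates = _aligned(
            split_multi(cell(row, "drug_start_dates"), sep), n_d, "drug start date", report_id
        )
        doses = _aligned(split_multi(cell(row, "drug_doses"), sep), n_d, "dose", report_id)
        indications = _aligned(
            split_multi(cell(row, "drug_indications"), sep), n_d, "indication", report_id
        )
        r_dates = _aligned(
            split_multi(cell(row, "reaction_start_dates"), sep),
            n_r, "reaction start date", report_id,
        )
        outcomes = _aligned(
            split_multi(cell(row, "reaction_outcomes"), sep), n_r, "outcome", report_id
        )

        norm = lambda v: normalize_missing(v, placeholders)  # noqa: E731
        sex = norm(cell(row, "sex"))
        age_text = norm(cell(row, "age"))
        country = norm(cell(row, "country"))
        qualification = norm(cell(row, "reporter_qualification"))
        report_type = norm(cell(row, "report_type"))
        narrative_present = any(
            norm(cell(row, f)) is not None
            for f in ("narrative", "reporter_comment", "sender_comment")
        )

        for i, drug in drugs:
            role = parse_drug_role(norm(roles[i]))
            drug_date = parse_date(norm(d_dates[i]))
            dose = norm(doses[i])
            indication = norm(indications[i])
            for j, reaction in reactions:
                records.append(
                    CombinationRecord(
                        report_id=report_id,
                        drug_name=drug,
                        reaction_term=reaction,
                        drug_role=role,
                        drug_start_date=drug_date,
                        dose_text=dose,
                        indication_text=indication,
                        reaction_start_date=parse_date(norm(r_dates[j])),
                        outcome_text=norm(outcomes[j]),
                        sex=sex,
                        age_text=age_text,
                        country=country,
                        reporter_qualification=qualification,
                        report_type=report_type,
                        narrative_present=narrative_present,
                    )
                )

    duplicates = sorted(rid for rid, n in ids_seen.items() if n > 1)
    if duplicates:
        raise ValidationError(
            f"duplicate report identifiers in line listing: {duplicates}"
        )
    return records
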