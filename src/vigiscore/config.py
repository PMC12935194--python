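"""Run-time configuration: column keywords, placeholders, penalties, dialect.

Line listings exported from EudraVigilance vary slightly in column titles and
in the wording used for absent values, so everything that identifies columns
or absence is configuration with sensible defaults, overridable from a YAML
file::

    placeholders: ["not available", "not specified", "unknown", ""]
    keywords:
      age: ["age"]
      drug_names: ["drug name", "substance"]
    penalties:
      sex: 0.3
    vaccine_terms: ["vaccine"]
    separator: "\\n"
    delimiter: ","

Penalty overrides change the meaning of the score and are logged prominently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import InputError, ValidationError

logger = logging.getLogger("vigiscore")

#: Semantic fields a line listing can provide, in resolution order.
SEMANTIC_FIELDS: tuple[str, ...] = (
    "report_id",
    "report_type",
    "reporter_qualification",
    "country",
    "sex",
    "age",
    "narrative",
    "reporter_comment",
    "sender_comment",
    "drug_names",
    "drug_roles",
    "drug_start_dates",
    "drug_doses",
    "drug_indications",
    "reaction_terms",
    "reaction_start_dates",
    "reaction_outcomes",
)

#: Fields that must resolve to a column for scoring to be possible.
REQUIRED_FIELDS: frozenset[str] = frozenset({"report_id", "drug_names", "reaction_terms"})

#: Case-insensitive substring keywords used to locate each semantic column.
DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "report_id": ("case identification", "case id", "report id", "identifier"),
    "report_type": ("report type",),
    "reporter_qualification": ("qualification",),
    "country": ("country",),
    "sex": ("sex", "gender"),
    "age": ("age",),
    "narrative": ("narrative",),
    "reporter_comment": ("reporter's comment", "reporter comment"),
    "sender_comment": ("sender's comment", "sender comment"),
    "drug_names": ("drug name", "substance", "medicinal product"),
    "drug_roles": ("characterisation", "drug role"),
    "drug_start_dates": ("drug start",),
    "drug_doses": ("dose",),
    "drug_indications": ("indication",),
    "reaction_terms": ("reaction pt", "reaction list", "reaction term"),
    "reaction_start_dates": ("reaction start",),
    "reaction_outcomes": ("outcome",),
}

#: Strings that encode absence, compared case-insensitively after trimming.
DEFAULT_PLACEHOLDERS: tuple[str, ...] = ("not available", "not specified", "unknown", "")

#: Drug-name substrings marking reports to drop before scoring.
DEFAULT_VACCINE_TERMS: tuple[str, ...] = (
    "vaccine",
    "vaccin",
    "toxoid",
    "hyposensit",
    "allergen extract",
)


@dataclass(frozen=True)
class Dialect:
    """How multi-valued cells and csv files are encoded."""

    separator: str = "\n"  # intra-cell separator between drugs / reactions
    delimiter: str = ","   # csv field delimiter
    sheet: int | str = 0   # xlsx sheet


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the scoring pipeline needs besides the listing itself."""

    keywords: Mapping[str, Sequence[str]] = field(default_factory=lambda: dict(DEFAULT_KEYWORDS))
    placeholders: Sequence[str] = DEFAULT_PLACEHOLDERS
    penalties: Mapping[str, float] | None = None  # None -> default scheme
    vaccine_terms: Sequence[str] = DEFAULT_VACCINE_TERMS
    dialect: Dialect = field(default_factory=Dialect)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file, merging over defaults."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"configuration file is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError("configuration file must contain a mapping at top level")

    cfg = PipelineConfig()
    if "keywords" in raw:
        merged = dict(DEFAULT_KEYWORDS)
        for fld, words in raw["keywords"].items():
            if fld not in SEMANTIC_FIELDS:
                raise ValidationError(f"unknown semantic field in keywords: {fld!r}")
            merged[fld] = tuple(str(w) for w in words)
        cfg = replace(cfg, keywords=merged)
    if "placeholders" in raw:
        cfg = replace(cfg, placeholders=tuple(str(p) for p in raw["placeholders"]))
    if "vaccine_terms" in raw:
        cfg = replace(cfg, vaccine_terms=tuple(str(t) for t in raw["vaccine_terms"]))
    if "penalties" in raw:
        overrides = {str(k): float(v) for k, v in raw["penalties"].items()}
        logger.warning(
            "penalty overrides in effect (%s): scores are no longer comparable "
            "with the default scheme",
            ", ".join(f"{k}={v}" for k, v in sorted(overrides.items())),
        )
        cfg = replace(cfg, penalties=overrides)
    dialect_kwargs = {}
    for key in ("separator", "delimiter", "sheet"):
        if key in raw:
            dialect_kwargs[key] = raw[key]
    if dialect_kwargs:
        cfg = replace(cfg, dialect=replace(cfg.dialect, **dialect_kwargs))
    return cfg
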