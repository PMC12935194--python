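"""Seeded synthetic line listings with known completeness ground truth.

Real EudraVigilance exports cannot be redistributed, so this module emits
structurally faithful stand-ins: one row per report, multi-valued drug and
reaction cells separated by the dialect separator, placeholder strings for
absent values, and DD/MM/YYYY dates with a configurable fraction of partial
(MM/YYYY or YYYY) emissions.  Every emitted combination comes with its true
category-presence pattern and true score, computed by an inline product that
is deliberately independent of the scoring module, so the full pipeline can
be verified against ground truth.

All randomness flows through one seeded NumPy generator; draws are consumed
in a fixed, documented order (per report: vaccine flag, drug/reaction
counts, report-level categories, dates, per-drug then per-reaction
attributes), so identical config + seed reproduce identical listings on any
platform.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .linelist import RawLineListing

# Ground-truth penalties: intentionally restated here (not imported from the
# scoring module) so the generator is an independent oracle for the pipeline.
_TRUTH_PENALTIES: dict[str, float] = {
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
_CATEGORIES = tuple(_TRUTH_PENALTIES)
_REPORT_LEVEL = ("sex", "age", "country", "primary_reporter", "report_type", "comments")
_COMBINATION_LEVEL = ("time_to_onset", "indication", "outcome", "dose")

#: Invented substance names — no real product names.
DRUG_LEXICON: tuple[str, ...] = (
    "Alphatensin", "Betamorol", "Cardiovin", "Dermaxol", "Epilentil",
    "Fluvorin", "Gastrolept", "Hepatizol", "Immunoral", "Juvantal",
    "Ketorivan", "Lipidrex", "Maximol", "Neurofen S", "Osteovit",
    "Pulmonex", "Quietan", "Renaldol", "Somnivar", "Thyroxal",
    "Urivent", "Vasopril", "Xanovir", "Zestratin", "Analgon",
    "Broncholyt", "Corticlear", "Diurecon", "Emetrizol", "Febrisan",
)
VACCINE_LEXICON: tuple[str, ...] = (
    "Influvax Vaccine", "Coronavax-19 Vaccine", "Tetanus Toxoid Adsorbed",
    "Pollenex Hyposensitisation Solution", "Gravivax Allergen Extract",
)
REACTION_LEXICON: tuple[str, ...] = (
    "Nausea", "Headache", "Pyrexia", "Rash", "Dizziness", "Vomiting",
    "Pruritus", "Urticaria", "Fatigue", "Diarrhoea", "Dyspnoea",
    "Hepatotoxicity", "Anaphylactic reaction", "Somnolence", "Tremor",
    "Alopecia", "Insomnia", "Cough", "Oedema peripheral", "Syncope",
)
INDICATION_LEXICON: tuple[str, ...] = (
    "Hypertension", "Depression", "Pain", "Epilepsy", "Diabetes mellitus",
    "Asthma", "Infection", "Hyperlipidaemia", "Anxiety", "Arthritis",
)
OUTCOME_LEXICON: tuple[str, ...] = (
    "Recovered/Resolved", "Recovering/Resolving",
    "Not recovered/Not resolved", "Recovered with sequelae", "Fatal",
)
_SEXES = ("Male", "Female")
_COUNTRIES = ("DE", "FR", "IT", "ES", "NL", "SE", "PL", "AT")
_QUALIFICATIONS = (
    "Physician", "Pharmacist", "Other Health Professional",
    "Consumer or other non health professional",
)
_DOSES_MG = (5, 10, 20, 25, 40, 50, 100, 250, 500)

#: Column labels of the emitted dialect (match the default keyword map).
COLUMNS: tuple[str, ...] = (
    "Worldwide Unique Case Identification",
    "Report Type",
    "Primary Source Qualification",
    "Primary Source Country for Regulatory Purposes",
    "Patient Sex",
    "Patient Age Group/Age",
    "Case Narrative",
    "Reporter's Comment",
    "Sender's Comment",
    "Drug Name",
    "Drug Characterisation",
    "Drug Start Date",
    "Drug Reported Dose",
    "Drug Indication",
    "Reaction List PT",
    "Reaction Start Date",
    "Reaction Outcome",
)

#: Default per-category absence probabilities: chosen once as a realistic
#: spontaneous-report profile (structured demographics mostly present, free
#: text and dates often absent), giving mean report scores around 0.4-0.6.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "time_to_onset": 0.50,
    "indication": 0.40,
    "outcome": 0.30,
    "sex": 0.05,
    "age": 0.20,
    "dose": 0.40,
    "country": 0.02,
    "primary_reporter": 0.05,
    "report_type": 0.01,
    "comments": 0.50,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which a synthetic listing is generated."""

    n_reports: int = 500
    seed: int = 0
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    drugs_per_report: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03}
    )
    reactions_per_report: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.10, 4: 0.04, 5: 0.01}
    )
    role_mix: Mapping[str, float] = field(
        default_factory=lambda: {"suspect": 0.75, "interacting": 0.05, "concomitant": 0.20}
    )
    vaccine_fraction: float = 0.05
    partial_date_fraction: float = 0.10
    placeholder_style: str = "Not available"

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValidationError("n_reports must be a positive integer")
        missing = set(_CATEGORIES) - set(self.missingness)
        if missing:
            raise ValidationError(f"missingness lacks categories: {sorted(missing)}")
        for name, probs in (
            ("missingness", self.missingness.values()),
            ("role_mix", self.role_mix.values()),
        ):
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")
        for name, dist in (
            ("drugs_per_report", self.drugs_per_report),
            ("reactions_per_report", self.reactions_per_report),
            ("role_mix", self.role_mix),
        ):
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError(f"{name} probabilities must sum to 1 (got {total})")
        for name, p in (
            ("vaccine_fraction", self.vaccine_fraction),
            ("partial_date_fraction", self.partial_date_fraction),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if set(self.role_mix) != {"suspect", "interacting", "concomitant"}:
            raise ValidationError("role_mix must cover exactly suspect/interacting/concomitant")


@dataclass
class GroundTruth:
    """True presence patterns and scores for every emitted combination.

    ``combinations`` has one row per (report, drug, reaction) with the ten
    presence booleans, the true score, the drug role, a ``scoreable`` flag
    (suspect/interacting) and the report's vaccine flag.  ``reports``
    aggregates the scoreable combinations (NaN mean/best when a report has
    none).  ``flips`` records perturbations applied by
    :func:`perturb_reference` (empty otherwise).
    """

    combinations: pd.DataFrame
    reports: pd.DataFrame
    flips: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["report_id", "drug_name", "reaction_term", "level", "category"]
        )
    )


def _truth_score(presence: Mapping[str, bool]) -> float:
    score = 1.0
    for cat, pen in _TRUTH_PENALTIES.items():
        if not presence[cat]:
            score *= 1.0 - pen
    return score


def _aggregate_reports(combos: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for rid, grp in combos.groupby("report_id", sort=True):
        scoreable = grp[grp["scoreable"]]
        rows.append(
            {
                "report_id": rid,
                "vaccine_report": bool(grp["vaccine_report"].iloc[0]),
                "n_scoreable": int(len(scoreable)),
                "true_mean": float(scoreable["score"].mean()) if len(scoreable) else float("nan"),
                "true_best": float(scoreable["score"].max()) if len(scoreable) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _date_str(d: datetime.date) -> str:
    return d.strftime("%d/%m/%Y")


def _partial_date_str(d: datetime.date, rng: np.random.Generator) -> str:
    return d.strftime("%m/%Y") if rng.random() < 0.5 else d.strftime("%Y")


def generate_linelisting(config: SyntheticConfig) -> tuple[RawLineListing, GroundTruth]:
    """Generate a listing in the documented dialect plus its ground truth.

    Date emission: a report's drug starts fall within 5 days of a base date
    and every reaction start at least 6 days after it, so a computable time
    to onset is always >= 0; TTO absence is driven purely by absent or
    partial date strings.  Each of the two dates of a pair is dropped with
    probability 1 - sqrt(1 - p_tto), making the pair's TTO-present
    probability equal 1 - p_tto when no partial dates are emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ph = config.placeholder_style
    p_tto = config.missingness["time_to_onset"]
    q_date = 1.0 - math.sqrt(1.0 - p_tto) if p_tto < 1.0 else 1.0

    drug_ks = sorted(config.drugs_per_report)
    drug_ps = [config.drugs_per_report[k] for k in drug_ks]
    react_ks = sorted(config.reactions_per_report)
    react_ps = [config.reactions_per_report[k] for k in react_ks]
    roles = ("suspect", "interacting", "concomitant")
    role_ps = [config.role_mix[r] for r in roles]
    epoch = datetime.date(2019, 1, 1)

    rows: list[dict[str, str]] = []
    truth_rows: list[dict[str, object]] = []
    for r in range(config.n_reports):
        rid = f"EV-SYN-{r + 1:06d}"
        vaccine = bool(rng.random() < config.vaccine_fraction)
        n_drugs = int(rng.choice(drug_ks, p=drug_ps))
        n_reactions = int(rng.choice(react_ks, p=react_ps))

        present: dict[str, bool] = {}
        for cat in _REPORT_LEVEL:
            present[cat] = bool(rng.random() >= config.missingness[cat])
        sex = str(rng.choice(_SEXES)) if present["sex"] else ph
        age = f"{int(rng.integers(1, 91))} Year(s)" if present["age"] else ph
        country = str(rng.choice(_COUNTRIES)) if present["country"] else ph
        qualification = str(rng.choice(_QUALIFICATIONS)) if present["primary_reporter"] else ph
        report_type = "Spontaneous" if present["report_type"] else ph
        if present["comments"]:
            narrative = "Patient developed the reaction during treatment."
            reporter_comment = (
                "Causal relationship considered possible." if rng.random() < 0.3 else ph
            )
        else:
            narrative = ph
            reporter_comment = ph
        sender_comment = ph

        base = epoch + datetime.timedelta(days=int(rng.integers(0, 701)))
        drug_names = list(rng.choice(DRUG_LEXICON, size=n_drugs, replace=False))
        if vaccine:
            drug_names[0] = str(rng.choice(VACCINE_LEXICON))

        drug_roles: list[str] = []
        drug_dates: list[str] = []
        drug_date_ok: list[bool] = []
        doses: list[str] = []
        dose_ok: list[bool] = []
        indications: list[str] = []
        indication_ok: list[bool] = []
        for _ in range(n_drugs):
            drug_roles.append(str(rng.choice(roles, p=role_ps)).capitalize())
            start = base + datetime.timedelta(days=int(rng.integers(0, 6)))
            if rng.random() < q_date:
                drug_dates.append(ph)
                drug_date_ok.append(False)
            elif rng.random() < config.partial_date_fraction:
                drug_dates.append(_partial_date_str(start, rng))
                drug_date_ok.append(False)
            else:
                drug_dates.append(_date_str(start))
                drug_date_ok.append(True)
            if rng.random() >= config.missingness["dose"]:
                doses.append(f"{int(rng.choice(_DOSES_MG))} mg")
                dose_ok.append(True)
            else:
                doses.append(ph)
                dose_ok.append(False)
            if rng.random() >= config.missingness["indication"]:
                indications.append(str(rng.choice(INDICATION_LEXICON)))
                indication_ok.append(True)
            else:
                indications.append(ph)
                indication_ok.append(False)

        reaction_terms = list(rng.choice(REACTION_LEXICON, size=n_reactions, replace=False))
        reaction_dates: list[str] = []
        reaction_date_ok: list[bool] = []
        outcomes: list[str] = []
        outcome_ok: list[bool] = []
        for _ in range(n_reactions):
            onset = base + datetime.timedelta(days=int(rng.integers(6, 37)))
            if rng.random() < q_date:
                reaction_dates.append(ph)
                reaction_date_ok.append(False)
            elif rng.random() < config.partial_date_fraction:
                reaction_dates.append(_partial_date_str(onset, rng))
                reaction_date_ok.append(False)
            else:
                reaction_dates.append(_date_str(onset))
                reaction_date_ok.append(True)
            if rng.random() >= config.missingness["outcome"]:
                outcomes.append(str(rng.choice(OUTCOME_LEXICON)))
                outcome_ok.append(True)
            else:
                outcomes.append(ph)
                outcome_ok.append(False)

        sep = "\n"
        rows.append(
            {
                COLUMNS[0]: rid,
                COLUMNS[1]: report_type,
                COLUMNS[2]: qualification,
                COLUMNS[3]: country,
                COLUMNS[4]: sex,
                COLUMNS[5]: age,
                COLUMNS[6]: narrative,
                COLUMNS[7]: reporter_comment,
                COLUMNS[8]: sender_comment,
                COLUMNS[9]: sep.join(drug_names),
                COLUMNS[10]: sep.join(drug_roles),
                COLUMNS[11]: sep.join(drug_dates),
                COLUMNS[12]: sep.join(doses),
                COLUMNS[13]: sep.join(indications),
                COLUMNS[14]: sep.join(reaction_terms),
                COLUMNS[15]: sep.join(reaction_dates),
                COLUMNS[16]: sep.join(outcomes),
            }
        )

        for i in range(n_drugs):
            for j in range(n_reactions):
                presence = {
                    "time_to_onset": drug_date_ok[i] and reaction_date_ok[j],
                    "indication": indication_ok[i],
                    "outcome": outcome_ok[j],
                    "sex": present["sex"],
                    "age": present["age"],
                    "dose": dose_ok[i],
                    "country": present["country"],
                    "primary_reporter": present["primary_reporter"],
                    "report_type": present["report_type"],
                    "comments": present["comments"],
                }
                truth_rows.append(
                    {
                        "report_id": rid,
                        "drug_name": drug_names[i],
                        "drug_role": drug_roles[i].lower(),
                        "reaction_term": reaction_terms[j],
                        "vaccine_report": vaccine,
                        "scoreable": drug_roles[i].lower() != "concomitant",
                        **presence,
                        "score": _truth_score(presence),
                    }
                )

    frame = pd.DataFrame(rows, columns=list(COLUMNS), dtype=str)
    combos = pd.DataFrame(truth_rows)
    return (
        RawLineListing(frame=frame, source_format="csv"),
        GroundTruth(combinations=combos, reports=_aggregate_reports(combos)),
    )


def perturb_reference(
    truth: GroundTruth,
    flip_config: Mapping[str, float],
    seed: int,
) -> GroundTruth:
    """Build a reference ground truth by flipping category presence.

    Report-level categories (sex, age, country, primary reporter, report
    type, comments) flip per report, consistently across all its
    combinations; combination-level categories (time to onset, indication,
    outcome, dose) flip per combination.  Reference scores are recomputed
    with the inline product, and every flip is recorded in ``flips``.
    """
    unknown = sorted(set(flip_config) - set(_CATEGORIES))
    if unknown:
        raise ValidationError(f"unknown categories in flip_config: {unknown}")
    if any(not (0.0 <= p <= 1.0) for p in flip_config.values()):
        raise ValidationError("flip probabilities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    combos = truth.combinations.copy(deep=True)
    flips: list[dict[str, object]] = []

    report_ids = list(dict.fromkeys(combos["report_id"]))
    for cat in _REPORT_LEVEL:
        p = flip_config.get(cat, 0.0)
        if p <= 0.0:
            continue
        for rid in report_ids:
            if rng.random() < p:
                mask = combos["report_id"] == rid
                combos.loc[mask, cat] = ~combos.loc[mask, cat].astype(bool)
                flips.append(
                    {"report_id": rid, "drug_name": "", "reaction_term": "",
                     "level": "report", "category": cat}
                )
    for cat in _COMBINATION_LEVEL:
        p = flip_config.get(cat, 0.0)
        if p <= 0.0:
            continue
        for idx in combos.index:
            if rng.random() < p:
                combos.loc[idx, cat] = not bool(combos.loc[idx, cat])
                flips.append(
                    {
                        "report_id": combos.loc[idx, "report_id"],
                        "drug_name": combos.loc[idx, "drug_name"],
                        "reaction_term": combos.loc[idx, "reaction_term"],
                        "level": "adr_drug",
                        "category": cat,
                    }
                )

    combos["score"] = [
        _truth_score({cat: bool(row[cat]) for cat in _CATEGORIES})
        for _, row in combos.iterrows()
    ]
    return GroundTruth(
        combinations=combos,
        reports=_aggregate_reports(combos),
        flips=pd.DataFrame(
            flips, columns=["report_id", "drug_name", "reaction_term", "level", "category"]
        ),
    )
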