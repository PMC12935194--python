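import datetime

import pytest

from vigiscore import (
    CombinationRecord,
    RawLineListing,
    SyntheticConfig,
    generate_linelisting,
)


def make_record(**overrides) -> CombinationRecord:
    """A fully populated combination record; override fields to poke holes."""
    base = dict(
        report_id="R1",
        drug_name="Alphatensin",
        reaction_term="Nausea",
        drug_role="suspect",
        drug_start_date=datetime.date(2020, 1, 1),
        dose_text="40 mg",
        indication_text="Hypertension",
        reaction_start_date=datetime.date(2020, 1, 5),
        outcome_text="Recovered/Resolved",
        sex="Female",
        age_text="34 Year(s)",
        country="DE",
        reporter_qualification="Physician",
        report_type="Spontaneous",
        narrative_present=True,
    )
    base.update(overrides)
    return CombinationRecord(**base)


@pytest.fixture
def full_record() -> CombinationRecord:
    return make_record()


@pytest.fixture(scope="session")
def synthetic_1000():
    """A 1,000-report synthetic listing with ground truth (seeded)."""
    cfg = SyntheticConfig(n_reports=1000, seed=20260920)
    return cfg, *generate_linelisting(cfg)


@pytest.fixture
def tiny_listing() -> RawLineListing:
    """Three single-combination reports written by hand."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "Worldwide Unique Case Identification": ["A-1", "A-2", "A-3"],
            "Report Type": ["Spontaneous", "Spontaneous", "Not available"],
            "Primary Source Qualification": ["Physician", "Not available", "Pharmacist"],
            "Primary Source Country for Regulatory Purposes": ["DE", "FR", "Not available"],
            "Patient Sex": ["Female", "Not available", "Male"],
            "Patient Age Group/Age": ["34 Year(s)", "Adult", "Not available"],
            "Case Narrative": ["Reaction after start.", "Not available", "Not available"],
            "Reporter's Comment": ["Not available"] * 3,
            "Sender's Comment": ["Not available"] * 3,
            "Drug Name": ["Alphatensin", "Betamorol", "Cardiovin"],
            "Drug Characterisation": ["Suspect", "Suspect", "Interacting"],
            "Drug Start Date": ["01/01/2020", "01/2020", "Not available"],
            "Drug Reported Dose": ["40 mg", "Not available", "two tablets"],
            "Drug Indication": ["Hypertension", "Not available", "Pain"],
            "Reaction List PT": ["Nausea", "Rash", "Headache"],
            "Reaction Start Date": ["05/01/2020", "10/01/2020", "Not available"],
            "Reaction Outcome": ["Recovered/Resolved", "Not available", "Fatal"],
        },
        dtype=str,
    )
    return RawLineListing(frame=frame, source_format="csv")
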