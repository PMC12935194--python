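"""The multiplicative completeness score and its aggregations."""

import datetime
import itertools

import numpy as np
import pytest

from vigiscore import (
    CATEGORIES,
    DEFAULT_PENALTIES,
    CategoryPresence,
    CombinationScore,
    PenaltyScheme,
    ValidationError,
    assess_presence,
    compute_time_to_onset,
    exclude_vaccines,
    score_combination,
    score_dataset,
    score_report,
    summarize_dataset,
)
from conftest import make_record

D = datetime.date


def brute_force_score(flags: dict[str, bool]) -> float:
    """Independent product oracle: multiply explicit literal factors."""
    factors = {
        "time_to_onset": 0.5, "indication": 0.7, "outcome": 0.7, "sex": 0.7,
        "age": 0.7, "dose": 0.9, "country": 0.9, "primary_reporter": 0.9,
        "report_type": 0.9, "comments": 0.9,
    }
    out = 1.0
    for cat, present in flags.items():
        if not present:
            out *= factors[cat]
    return out


class TestPenaltyScheme:
    def test_default_floor_is_0_0709(self):
        assert round(PenaltyScheme.default().floor(), 4) == 0.0709

    def test_scheme_requires_exactly_ten_categories(self):
        with pytest.raises(ValidationError):
            PenaltyScheme(penalties={"sex": 0.3})
        bad = dict(DEFAULT_PENALTIES, sex=1.0)
        with pytest.raises(ValidationError):
            PenaltyScheme(penalties=bad)

    def test_override_merges_over_defaults(self):
        scheme = PenaltyScheme.from_mapping({"sex": 0.2})
        assert scheme.penalties["sex"] == 0.2
        assert scheme.penalties["age"] == 0.3


class TestTimeToOnset:
    @pytest.mark.parametrize(
        "drug,reaction,expected",
        [
            (D(2020, 1, 1), D(2020, 1, 5), 4),
            (D(2020, 1, 5), D(2020, 1, 1), None),  # negative -> unavailable
            (D(2020, 1, 5), D(2020, 1, 5), 0),     # same day counts
            (None, D(2020, 1, 5), None),
            (D(2020, 1, 1), None, None),
            (None, None, None),
        ],
    )
    def test_non_negative_day_difference_only(self, drug, reaction, expected):
        assert compute_time_to_onset(drug, reaction) == expected

    def test_exhaustive_date_pairs_within_window(self):
        """Oracle: present iff reaction is on/after drug start, all pairs."""
        days = [D(2020, 1, 1) + datetime.timedelta(days=i) for i in range(10)]
        for a, b in itertools.product(days, days):
            tto = compute_time_to_onset(a, b)
            if b >= a:
                assert tto == (b - a).days >= 0
            else:
                assert tto is None


class TestAssessPresence:
    def test_fully_populated_record_has_all_ten_flags(self, full_record):
        assert assess_presence(full_record) == CategoryPresence.all_present()

    @pytest.mark.parametrize(
        "override,category",
        [
            (dict(drug_start_date=None), "time_to_onset"),
            (dict(reaction_start_date=None), "time_to_onset"),
            (dict(indication_text=None), "indication"),
            (dict(outcome_text=None), "outcome"),
            (dict(sex=None), "sex"),
            (dict(age_text=None), "age"),
            (dict(age_text="Adult"), "age"),  # group label is not numeric age
            (dict(dose_text=None), "dose"),
            (dict(dose_text="two tablets"), "dose"),  # no numeric token
            (dict(country=None), "country"),
            (dict(reporter_qualification=None), "primary_reporter"),
            (dict(report_type=None), "report_type"),
            (dict(narrative_present=False), "comments"),
        ],
    )
    def test_single_absence_clears_exactly_one_flag(self, override, category):
        presence = assess_presence(make_record(**override))
        assert presence.absent_categories() == (category,)

    @pytest.mark.parametrize("dose", ["40 mg", "2 tablets", "0.5 ml", "1000 units"])
    def test_any_numeric_dose_counts_regardless_of_unit(self, dose):
        assert assess_presence(make_record(dose_text=dose)).dose

    def test_reversed_dates_clear_time_to_onset(self):
        rec = make_record(
            drug_start_date=D(2020, 1, 5), reaction_start_date=D(2020, 1, 1)
        )
        assert assess_presence(rec).absent_categories() == ("time_to_onset",)


class TestScoreCombination:
    def test_all_absent_floor(self):
        assert score_combination(CategoryPresence.all_absent()) == pytest.approx(
            0.0709, abs=5e-5
        )

    def test_all_present_ceiling(self):
        assert score_combination(CategoryPresence.all_present()) == 1.0

    def test_only_sex_absent_is_0_70(self):
        presence = CategoryPresence(**{c: c != "sex" for c in CATEGORIES})
        assert score_combination(presence) == pytest.approx(0.70)

    def test_tto_and_age_absent_is_0_35(self):
        presence = CategoryPresence(
            **{c: c not in ("time_to_onset", "age") for c in CATEGORIES}
        )
        assert score_combination(presence) == pytest.approx(0.35)

    def test_brute_force_oracle_over_all_1024_patterns(self):
        for bits in itertools.product([False, True], repeat=10):
            flags = dict(zip(CATEGORIES, bits))
            got = score_combination(CategoryPresence(**flags))
            assert got == pytest.approx(brute_force_score(flags), abs=1e-12)
            assert 0.0708 <= got <= 1.0

    def test_bounds_attained_only_at_extremes(self):
        floor = PenaltyScheme.default().floor()
        for bits in itertools.product([False, True], repeat=10):
            got = score_combination(CategoryPresence(**dict(zip(CATEGORIES, bits))))
            if all(bits):
                assert got == 1.0
            elif not any(bits):
                assert got == pytest.approx(floor, abs=1e-15)
            else:
                assert floor < got < 1.0

    def test_flipping_any_category_to_present_strictly_increases(self):
        scheme = PenaltyScheme.default()
        for bits in itertools.product([False, True], repeat=10):
            flags = dict(zip(CATEGORIES, bits))
            base = score_combination(CategoryPresence(**flags), scheme)
            for cat in CATEGORIES:
                if not flags[cat]:
                    better = score_combination(
                        CategoryPresence(**{**flags, cat: True}), scheme
                    )
                    assert better == pytest.approx(
                        base / (1 - scheme.penalties[cat]), rel=1e-12
                    )
                    assert better > base


def combo(rid: str, score: float, drug="DrugA", reaction="Nausea") -> CombinationScore:
    # reverse-engineer no presence pattern; aggregation only uses .score
    return CombinationScore(
        report_id=rid, drug_name=drug, reaction_term=reaction,
        drug_role="suspect", presence=CategoryPresence.all_present(), score=score,
    )


class TestScoreReport:
    def test_mean_best_and_distinct(self):
        rep = score_report([combo("R", 0.5), combo("R", 0.7, drug="DrugB")])
        assert rep.mean_score == pytest.approx(0.6)
        assert rep.best_score == pytest.approx(0.7)
        assert rep.n_combinations == 2
        assert rep.n_distinct_scores == 2
        assert not rep.well_documented

    def test_single_combination_identity(self):
        rep = score_report([combo("R", 0.9)])
        assert rep.mean_score == rep.best_score == pytest.approx(0.9)
        assert rep.well_documented

    def test_threshold_is_inclusive_at_0_8(self):
        assert score_report([combo("R", 0.8)]).well_documented
        assert not score_report([combo("R", 0.7999)]).well_documented

    def test_distinctness_uses_two_decimal_rounding(self):
        rep = score_report(
            [combo("R", 0.35 + 1e-12), combo("R", 0.35, drug="DrugB")]
        )
        assert rep.n_distinct_scores == 1

    def test_duplicating_mean_valued_combination_keeps_mean(self):
        combos = [combo("R", 0.5), combo("R", 0.7, drug="B")]
        mean = score_report(combos).mean_score
        widened = combos + [combo("R", mean, drug="C")]
        assert score_report(widened).mean_score == pytest.approx(mean)

    def test_mixed_reports_rejected(self):
        with pytest.raises(ValidationError):
            score_report([combo("R1", 0.5), combo("R2", 0.5)])


class TestExcludeVaccines:
    TERMS = ("vaccine", "hyposensit")

    def test_whole_report_removed_on_one_matching_drug(self):
        records = [
            make_record(report_id="V1", drug_name="COVID-19 VACCINE X"),
            make_record(report_id="V1", drug_name="Paracetamol"),
            make_record(report_id="K1", drug_name="Paracetamol"),
        ]
        kept = exclude_vaccines(records, self.TERMS)
        assert {r.report_id for r in kept} == {"K1"}

    def test_empty_term_list_is_identity(self):
        records = [make_record(report_id="V1", drug_name="Vaccine X")]
        assert exclude_vaccines(records, ()) == records

    def test_generator_vaccine_reports_all_and_only_removed(self, synthetic_1000):
        from vigiscore import PipelineConfig, expand_combinations, resolve_columns

        _, listing, truth = synthetic_1000
        records = expand_combinations(listing, resolve_columns(listing))
        kept = exclude_vaccines(records, PipelineConfig().vaccine_terms)
        kept_ids = {r.report_id for r in kept}
        vaccine_ids = set(
            truth.reports[truth.reports.vaccine_report].report_id
        )
        assert vaccine_ids
        assert kept_ids == set(truth.reports.report_id) - vaccine_ids


class TestScoreDataset:
    def test_counts_and_order(self):
        records = [
            make_record(report_id="B"), make_record(report_id="C"),
            make_record(report_id="A"),
        ]
        combos, reports = score_dataset(records)
        assert [r.report_id for r in reports] == ["A", "B", "C"]
        assert len(combos) == 3

    def test_permutation_yields_identical_score_multiset(self, synthetic_1000):
        from vigiscore import expand_combinations, resolve_columns

        _, listing, _ = synthetic_1000
        records = expand_combinations(listing, resolve_columns(listing))[:300]
        _, fwd = score_dataset(records)
        _, rev = score_dataset(list(reversed(records)))
        assert sorted(r.mean_score for r in fwd) == sorted(r.mean_score for r in rev)

    def test_concomitant_combinations_excluded_from_mean(self):
        records = [
            make_record(report_id="R", drug_name="A"),
            make_record(report_id="R", drug_name="B", drug_role="concomitant",
                        sex=None),
        ]
        combos, reports = score_dataset(records)
        assert len(combos) == 1
        assert reports[0].mean_score == 1.0

    def test_concomitant_only_report_excluded_with_warning(self, caplog):
        records = [make_record(report_id="R", drug_role="concomitant")]
        with caplog.at_level("WARNING", logger="vigiscore"):
            combos, reports = score_dataset(records)
        assert combos == [] and reports == []
        assert any("concomitant" in m for m in caplog.messages)


class TestSummarize:
    def test_small_hand_computed_summary(self):
        reports = [
            score_report([combo("A", 0.2)]),
            score_report([combo("B", 0.5)]),
            score_report([combo("C", 0.8)]),
        ]
        s = summarize_dataset(reports)
        assert s.mean == pytest.approx(0.5)
        assert s.median == pytest.approx(0.5)
        assert s.n_well_documented == 1  # threshold inclusive
        assert s.sd == pytest.approx(np.std([0.2, 0.5, 0.8], ddof=1))

    def test_identical_reports_have_zero_sd(self):
        reports = [score_report([combo(f"R{i}", 0.5)]) for i in range(4)]
        assert summarize_dataset(reports).sd == 0.0

    def test_empty_input_is_fatal(self):
        with pytest.raises(ValidationError):
            summarize_dataset([])

    def test_summary_matches_independent_recomputation(self, synthetic_1000):
        from vigiscore import score_line_listing

        _, listing, _ = synthetic_1000
        result = score_line_listing(listing)
        s = result.summary
        means = np.array([r.mean_score for r in result.report_scores])
        assert s.n_reports == len(means)
        assert s.mean == pytest.approx(means.mean())
        assert s.sd == pytest.approx(means.std(ddof=1))
        assert s.median == pytest.approx(np.median(means))
        assert (s.q1, s.q3) == (
            pytest.approx(np.percentile(means, 25)),
            pytest.approx(np.percentile(means, 75)),
        )
        assert s.n_well_documented == int((means >= 0.8).sum())
        assert sum(s.distinct_value_histogram.values()) == s.n_reports
        hist = {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
        for r in result.report_scores:
            hist[str(r.n_distinct_scores) if r.n_distinct_scores < 5 else ">=5"] += 1
        assert dict(s.distinct_value_histogram) == hist
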