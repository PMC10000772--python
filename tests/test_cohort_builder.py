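"""Screening, exclusion, index-dating and characterization rules."""

import pandas as pd
import pytest

from artclaims import CohortSpec, build_cohort
from artclaims.cohort_builder import (
    apply_exclusions,
    characterize_baseline,
    index_and_label,
    screen_art_patients,
)

from conftest import make_tables, monthly_dispensations


def _demo(pid, birth="1970-06-15", **kw):
    return {"patient_id": pid, "birth_date": birth, **kw}


class TestScreening:
    def test_minor_at_first_art_excluded(self, default_spec):
        tables = make_tables(
            [_demo("P1", birth="2000-06-01"), _demo("P2", birth="1999-06-01")],
            monthly_dispensations("P1", "2017-06-01", 3)
            + monthly_dispensations("P2", "2017-06-01", 3),
        )
        # P1 is 17.0 y at first ART, P2 just turned 18
        ids = screen_art_patients(tables, default_spec)
        assert ids == {"P2"}

    def test_non_art_dispensations_do_not_qualify(self, default_spec):
        tables = make_tables(
            [_demo("P1")],
            monthly_dispensations("P1", "2017-06-01", 5, atc="C10AA05"),
        )
        assert screen_art_patients(tables, default_spec) == set()

    def test_art_outside_inclusion_window_ignored(self, default_spec):
        tables = make_tables(
            [_demo("P1")],
            monthly_dispensations("P1", "2014-02-01", 3),
        )
        assert screen_art_patients(tables, default_spec) == set()

    def test_screened_count_matches_ground_truth(self, gen_tables, default_spec):
        ids = screen_art_patients(gen_tables, default_spec)
        truth_ids = set(gen_tables.ground_truth["patient_id"])
        assert ids == truth_ids  # every generated patient is an adult ART user


class TestExclusions:
    def test_single_prescription_excluded(self, default_spec):
        tables = make_tables(
            [_demo("P1")], monthly_dispensations("P1", "2017-06-01", 1)
        )
        kept, log = apply_exclusions({"P1"}, tables, default_spec)
        assert kept == set()
        assert log["exclusion_rule"].tolist() == ["single_prescription"]

    def test_gap_over_one_year_excluded(self, default_spec):
        tables = make_tables(
            [_demo("P1")],
            monthly_dispensations("P1", "2016-01-01", 1)
            + monthly_dispensations("P1", "2017-02-05", 1),  # 401 days later
        )
        kept, log = apply_exclusions({"P1"}, tables, default_spec)
        assert kept == set()
        assert log["exclusion_rule"].tolist() == ["gap"]

    def test_regular_refills_retained(self, default_spec):
        tables = make_tables(
            [_demo("P1")], monthly_dispensations("P1", "2016-01-01", 24)
        )
        kept, _ = apply_exclusions({"P1"}, tables, default_spec)
        assert kept == {"P1"}

    def test_transfer_out_excluded(self, default_spec):
        tables = make_tables(
            [_demo("P1", transfer_out_date="2018-05-01")],
            monthly_dispensations("P1", "2016-01-01", 24),
        )
        kept, log = apply_exclusions({"P1"}, tables, default_spec)
        assert kept == set()
        assert log["exclusion_rule"].tolist() == ["transfer"]


class TestIndexAndLabel:
    def test_str_vs_mtr_from_first_taf_dispensation(self, default_spec):
        tables = make_tables(
            [_demo("P1"), _demo("P2")],
            monthly_dispensations("P1", "2017-06-01", 13, atc="J05AR20")
            + monthly_dispensations("P2", "2017-06-01", 13, atc="J05AF13"),
        )
        cohort = index_and_label({"P1", "P2"}, tables, default_spec)
        sub = cohort.set_index("patient_id")["taf_subtype"]
        assert sub["P1"] == "STR" and sub["P2"] == "MTR"

    def test_prior_non_taf_art_makes_switcher(self, default_spec):
        prior = monthly_dispensations("P1", "2017-02-21", 1, atc="J05AR13")
        taf = monthly_dispensations("P1", "2017-06-01", 13, atc="J05AR20")
        tables = make_tables([_demo("P1")], prior + taf)
        cohort = index_and_label({"P1"}, tables, default_spec)
        assert cohort.loc[0, "experience"] == "switcher"
        assert cohort.loc[0, "index_date"] == pd.Timestamp("2017-06-01")

    def test_no_prior_art_is_naive(self, default_spec):
        tables = make_tables(
            [_demo("P1")], monthly_dispensations("P1", "2017-06-01", 13)
        )
        cohort = index_and_label({"P1"}, tables, default_spec)
        assert cohort.loc[0, "experience"] == "naive"

    def test_lookback_is_half_open_at_index(self, default_spec):
        """Another ART product dispensed ON the index date keeps naive status."""
        same_day = monthly_dispensations("P1", "2017-06-01", 1, atc="J05AX12")
        taf = monthly_dispensations("P1", "2017-06-01", 13, atc="J05AR20")
        tables = make_tables([_demo("P1")], same_day + taf)
        cohort = index_and_label({"P1"}, tables, default_spec)
        assert cohort.loc[0, "experience"] == "naive"

    def test_age_classes(self, default_spec):
        tables = make_tables(
            [_demo("P1", birth="1983-01-01")],  # 34.4 y at index
            monthly_dispensations("P1", "2017-06-01", 13),
        )
        cohort = index_and_label({"P1"}, tables, default_spec)
        assert cohort.loc[0, "age_class"] == "<36"
        assert cohort.loc[0, "age_class_glm"] == "<=50"


class TestCharacterization:
    def _cohort_and_tables(self, hospital, pharmacy=()):
        taf = monthly_dispensations("P1", "2017-06-01", 13, atc="J05AR20")
        tables = make_tables([_demo("P1")], list(pharmacy) + taf, hospital)
        spec = CohortSpec()
        cohort = index_and_label({"P1"}, tables, spec)
        return characterize_baseline(cohort, tables, spec), tables

    def test_single_diabetes_admission_scores_one(self, default_spec):
        base, _ = self._cohort_and_tables(
            [{"patient_id": "P1", "admission_date": "2017-01-10",
              "discharge_date": "2017-01-12", "icd9_codes": "250.00"}]
        )
        assert bool(base.loc[0, "diabetes"])
        assert base.loc[0, "cci"] == 1

    def test_no_baseline_events_scores_zero(self, default_spec):
        base, _ = self._cohort_and_tables([])
        flags = base.drop(columns=["patient_id", "cci"]).iloc[0]
        assert not flags.any()
        assert base.loc[0, "cci"] == 0

    def test_metastatic_plus_diabetes_scores_seven(self, default_spec):
        base, _ = self._cohort_and_tables(
            [{"patient_id": "P1", "admission_date": "2017-01-10",
              "discharge_date": "2017-01-20", "icd9_codes": "197.0|250.00"}]
        )
        assert base.loc[0, "cci"] == 7  # metastatic (6) + uncomplicated diabetes (1)

    def test_post_index_events_are_ignored(self, default_spec):
        base, _ = self._cohort_and_tables(
            [{"patient_id": "P1", "admission_date": "2017-06-01",
              "discharge_date": "2017-06-03", "icd9_codes": "250.00"},
             {"patient_id": "P1", "admission_date": "2018-01-10",
              "discharge_date": "2018-01-12", "icd9_codes": "197.0"}],
            pharmacy=monthly_dispensations(
                "P1", "2017-07-01", 2, atc="C10AA05"
            ),
        )
        flags = base.drop(columns=["patient_id", "cci"]).iloc[0]
        assert not flags.any()
        assert base.loc[0, "cci"] == 0

    def test_atc_evidence_flags_condition(self, default_spec):
        base, _ = self._cohort_and_tables(
            [], pharmacy=monthly_dispensations(
                "P1", "2017-01-15", 1, atc="C10AA05"
            ),
        )
        assert bool(base.loc[0, "dyslipidemia"])
        assert base.loc[0, "cci"] == 0  # drug evidence never feeds the ICD score


def test_labels_agree_with_ground_truth(gen_tables, default_spec):
    """Regimen subtype and naive/switcher labels match the planted truth."""
    res = build_cohort(gen_tables, default_spec)
    merged = res.cohort.merge(gen_tables.ground_truth, on="patient_id")
    taf = merged[merged["is_taf"]]
    assert len(taf) == len(res.cohort)
    agree_reg = (taf["taf_subtype"] == taf["regimen"]).mean()
    agree_exp = (taf["experience_x"] == taf["experience_y"]).mean()
    assert agree_reg >= 0.99
    assert agree_exp >= 0.99
    # both label systems partition the cohort
    assert set(taf["taf_subtype"]) <= {"MTR", "STR"}
    assert set(taf["experience_x"]) <= {"naive", "switcher"}
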