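"""Annualized tallies, cent-exact accounting, outlier rule, stratification."""

import numpy as np
import pandas as pd
import pytest

from artclaims import (
    CohortSpec,
    GeneratorConfig,
    build_cohort,
    compute_utilization,
    exclude_outliers,
    generate_cohort_tables,
    stratify_costs,
    tally_resources,
)
from artclaims.resource_costs import COST_ITEMS

from conftest import make_tables, monthly_dispensations


def _one_patient_cohort(followup_days=800, died=False):
    return pd.DataFrame({
        "patient_id": ["P1"],
        "index_date": [pd.Timestamp("2017-06-01")],
        "followup_days": [followup_days],
        "died": [died],
    })


class TestTally:
    def test_monthly_art_gives_12_per_year(self, default_spec):
        tables = make_tables(
            [{"patient_id": "P1"}],
            monthly_dispensations("P1", "2017-06-01", 12, cost_eur=500.0),
        )
        out = tally_resources(_one_patient_cohort(), tables, default_spec)
        row = out.iloc[0]
        assert row["n_hiv_drug_disp_py"] == 12
        assert row["hiv_drugs_eur_py"] == pytest.approx(6000.0)
        assert row["person_years"] == 1.0

    def test_outpatient_annualization_over_two_years(self, default_spec):
        visits = [
            {"patient_id": "P1",
             "service_date": pd.Timestamp("2017-06-01") + pd.Timedelta(days=70 * i)}
            for i in range(10)
        ]
        tables = make_tables([{"patient_id": "P1"}], outpatient=visits)
        out = tally_resources(
            _one_patient_cohort(730), tables, default_spec, window="all_followup"
        )
        assert out.iloc[0]["n_outpatient_py"] == pytest.approx(5.0, abs=0.01)

    def test_hiv_drg_admission_costed_as_hiv_hosp(self, default_spec):
        tables = make_tables(
            [{"patient_id": "P1"}],
            hospital=[{"patient_id": "P1", "admission_date": "2017-08-01",
                       "discharge_date": "2017-08-05", "drg_code": "489",
                       "tariff_eur": 5000.0}],
        )
        out = tally_resources(_one_patient_cohort(), tables, default_spec)
        row = out.iloc[0]
        assert row["n_hiv_hosp"] == 1
        assert row["hiv_hosp_eur_py"] == pytest.approx(5000.0)
        assert row["other_hosp_eur_py"] == 0.0

    def test_unknown_drg_counts_as_other_hospitalization(self, default_spec):
        tables = make_tables(
            [{"patient_id": "P1"}],
            hospital=[{"patient_id": "P1", "admission_date": "2017-08-01",
                       "discharge_date": "2017-08-05", "drg_code": "999",
                       "tariff_eur": 700.0}],
        )
        row = tally_resources(_one_patient_cohort(), tables, default_spec).iloc[0]
        assert row["n_other_hosp"] == 1 and row["n_hiv_hosp"] == 0

    def test_dead_in_window_patient_excluded(self, default_spec):
        tables = make_tables(
            [{"patient_id": "P1", "death_date": "2017-09-01"}],
            monthly_dispensations("P1", "2017-06-01", 3),
        )
        out = tally_resources(
            _one_patient_cohort(92, died=True), tables, default_spec
        )
        assert out.empty

    def test_item_costs_sum_to_total_in_cents(self, gen_tables, default_spec):
        cohort = build_cohort(gen_tables, default_spec).cohort
        for window in ("first_year", "all_followup"):
            out = tally_resources(cohort, gen_tables, default_spec, window=window)
            items = sum(out[f"{i}_cents"] for i in COST_ITEMS)
            assert (items == out["total_cents"]).all()
            annual = sum(out[f"{i}_eur_py"] for i in COST_ITEMS)
            assert np.allclose(annual, out["total_eur_py"], atol=0.005)


class TestOutliers:
    def test_worked_fixture_excludes_none(self):
        df = pd.DataFrame({"patient_id": list("abcd"),
                           "total_eur_py": [1.0, 1.0, 1.0, 100.0]})
        res = exclude_outliers(df)
        assert res.mean == pytest.approx(25.75)
        assert res.sd == pytest.approx(49.5, abs=0.01)
        assert res.threshold == pytest.approx(174.25, abs=0.01)
        assert res.excluded_ids == []
        assert len(res.retained) == 4

    def test_equal_totals_exclude_none(self):
        df = pd.DataFrame({"patient_id": list("abc"),
                           "total_eur_py": [5.0, 5.0, 5.0]})
        res = exclude_outliers(df)
        assert res.excluded_ids == []  # threshold == mean, strict inequality

    def test_single_extreme_patient_excluded(self):
        rng = np.random.default_rng(4)
        totals = 1000 + rng.normal(0, 10, size=1000)
        totals[137] = 10 * totals.mean()
        df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(1000)],
                           "total_eur_py": totals})
        res = exclude_outliers(df)
        assert res.excluded_ids == ["p137"]

    def test_fewer_than_two_patients_skips_rule(self):
        df = pd.DataFrame({"patient_id": ["a"], "total_eur_py": [1.0]})
        res = exclude_outliers(df)
        assert len(res.retained) == 1 and res.excluded_ids == []


class TestStratification:
    @pytest.fixture()
    def breakdowns(self, gen_tables, default_spec):
        cohort = build_cohort(gen_tables, default_spec).cohort
        costs = tally_resources(cohort, gen_tables, default_spec)
        return cohort, exclude_outliers(costs).retained

    def test_stratum_means_recombine_to_overall(self, breakdowns, default_spec):
        cohort, retained = breakdowns
        labels = cohort.set_index("patient_id")["taf_subtype"]
        table = stratify_costs(retained, labels)
        pooled = (table["total_eur_py_mean"] * table["n"]).sum() / table["n"].sum()
        assert pooled == pytest.approx(retained["total_eur_py"].mean())

    def test_single_stratum_equals_unstratified_summary(self, breakdowns):
        _, retained = breakdowns
        labels = pd.Series("all", index=retained["patient_id"])
        table = stratify_costs(retained, labels)
        assert len(table) == 1
        assert table.loc[0, "n"] == len(retained)
        assert table.loc[0, "total_eur_py_mean"] == pytest.approx(
            retained["total_eur_py"].mean()
        )

    def test_identical_strata_compare_near_p1(self, breakdowns):
        _, retained = breakdowns
        doubled = pd.concat([
            retained.assign(patient_id=retained["patient_id"] + "_a"),
            retained.assign(patient_id=retained["patient_id"] + "_b"),
        ])
        labels = pd.Series(
            ["x"] * len(retained) + ["y"] * len(retained),
            index=doubled["patient_id"],
        )
        table = stratify_costs(doubled, labels, compare=("x", "y"))
        assert table["total_eur_py_p"].iloc[0] == pytest.approx(1.0)

    def test_uncovered_patient_raises(self, breakdowns):
        _, retained = breakdowns
        labels = pd.Series("g", index=retained["patient_id"][:-1])
        with pytest.raises(ValueError):
            stratify_costs(retained, labels)


def test_nonpersistent_hiv_hosp_costs_higher(default_spec):
    """The persistence-dependent admission rates put the cost gap in the
    configured direction: non-persistent patients accrue more HIV-related
    hospitalization cost per year."""
    hits = 0
    for seed in (101, 102, 103):
        cfg = GeneratorConfig(n_patients=2000, taf_fraction=1.0, seed=seed)
        tables = generate_cohort_tables(cfg)
        cohort = build_cohort(tables, default_spec).cohort
        util = compute_utilization(cohort, tables, default_spec)
        costs = tally_resources(cohort, tables, default_spec)
        retained = exclude_outliers(costs).retained
        merged = retained.merge(util[["patient_id", "status"]], on="patient_id")
        persistent = merged[merged["status"] == "persistent"]
        nonpersistent = merged[merged["status"] != "persistent"]
        gap = (nonpersistent["hiv_hosp_eur_py"].mean()
               - persistent["hiv_hosp_eur_py"].mean())
        hits += gap > 0
    assert hits == 3
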