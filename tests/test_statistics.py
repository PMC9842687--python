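from datetime import date

import pandas as pd
import pytest

from rtdet.io_model import (
    AppointmentRecord,
    DateWindow,
    FractionRecord,
    Intent,
    Task,
)
from rtdet.statistics import (
    GroupResourceStats,
    PoolingMap,
    export_application_dataset,
    group_by_diagnosis_intent,
    load_resource_stats,
    monthly_inflow,
    resource_stats,
    top_coverage,
)
from rtdet.substitution import substitute_intents
from rtdet.synthetic import CohortSpec, generate_cohort
from rtdet.cleaning import clean_table

from .conftest import make_referral


class TestPoolingMap:
    def test_metastasis_categories_pool_together(self):
        pm = PoolingMap()
        assert pm("C77") == pm("C78") == pm("C79") == "C77-79"
        assert pm("C50") == "C50"
        assert pm("c50.1") == "C50"  # subcode pooled onto its category

    def test_identity_map_keeps_categories_separate(self):
        pm = PoolingMap.identity()
        assert pm("C77") == "C77" and pm("C79") == "C79"


class TestGroupByDiagnosisIntent:
    def test_single_group_covers_everything(self):
        refs = [make_referral(i) for i in range(10)]
        gt = group_by_diagnosis_intent(refs)
        assert len(gt.rows) == 1
        row = gt.rows.iloc[0]
        assert (row["group"], row["intent"], row["patients"], row["pct"]) == (
            "C50",
            "curative",
            10,
            100,
        )

    def test_empty_input_gives_empty_table(self):
        gt = group_by_diagnosis_intent([])
        assert gt.total_patients == 0 and gt.rows.empty

    def test_patient_with_multiple_referrals_counted_once_at_earliest(self):
        refs = [
            make_referral("P1", diagnosis="C61", day=9),
            make_referral("P1", diagnosis="C50", day=2),  # earliest wins
            make_referral("P2", diagnosis="C61", day=1),
        ]
        gt = group_by_diagnosis_intent(refs)
        counts = dict(zip(gt.rows["group"], gt.rows["patients"]))
        assert counts == {"C50": 1, "C61": 1}
        assert gt.total_patients == 2

    def test_pct_column_sums_to_100_within_rounding(self, cleaned_study_referrals):
        records, _ = cleaned_study_referrals
        gt = group_by_diagnosis_intent(substitute_intents(records, "ratio"))
        assert gt.rows["patients"].sum() == gt.total_patients
        assert abs(gt.rows["pct"].sum() - 100) <= len(gt.rows)
        assert list(gt.rows["patients"]) == sorted(gt.rows["patients"], reverse=True)


class TestTopCoverage:
    def test_prefix_property(self, cleaned_study_referrals):
        records, _ = cleaned_study_referrals
        gt = group_by_diagnosis_intent(substitute_intents(records, "ratio"))
        top5, sum5, _ = top_coverage(gt, 5)
        top10, sum10, _ = top_coverage(gt, 10)
        assert top5.equals(top10.head(5))
        assert sum5 <= sum10

    def test_n_beyond_row_count_covers_all(self):
        refs = [make_referral(i, diagnosis=d) for i, d in enumerate(["C50", "C61"])]
        gt = group_by_diagnosis_intent(refs)
        top, total, cov = top_coverage(gt, 99)
        assert len(top) == 2 and total == 2 and cov == 100


class TestResourceStats:
    def test_single_patient_cell(self):
        refs = [make_referral("P1")]
        apps = [
            AppointmentRecord(f"A{i}", "P1", Task.MOULD, date(2015, 2, 1 + i))
            for i in range(2)
        ]
        fracs = [FractionRecord("P1", date(2015, 3, 1 + i)) for i in range(3)]
        rs = resource_stats(refs, apps, fracs)
        row = rs.table.loc[("C50", "curative")]
        assert (row["patients"], row["mould"], row["fractions"]) == (1, 2, 3)

    def test_no_appointments_gives_zero_columns(self):
        rs = resource_stats([make_referral("P1")], [], [])
        row = rs.table.loc[("C50", "curative")]
        assert row[["mould", "ct", "mri", "pet", "tp", "qa", "fractions"]].sum() == 0

    def test_ct_pools_both_sites_and_orphans_go_to_other(self):
        refs = [make_referral("P1")]
        apps = [
            AppointmentRecord("A1", "P1", Task.CT_SITE1, date(2015, 2, 1)),
            AppointmentRecord("A2", "P1", Task.CT_SITE2, date(2015, 2, 2)),
            AppointmentRecord("A3", "GHOST", Task.QA, date(2015, 2, 3)),
        ]
        rs = resource_stats(refs, apps, [])
        assert rs.table.loc[("C50", "curative"), "ct"] == 2
        assert rs.table.loc[("Other", ""), "qa"] == 1

    def test_attribution_conservation_on_generated_cohort(self):
        result = generate_cohort(CohortSpec(n_patients=250), seed=11)
        refs, _ = clean_table(result.referrals)
        apps, _ = clean_table(result.appointments)
        fracs, _ = clean_table(result.fractions)
        rs = resource_stats(refs, apps, fracs, PoolingMap.identity())
        totals = rs.totals()
        assert totals["patients"] == len({r.patient_id for r in refs})
        assert totals["fractions"] == len(fracs)
        app_cols = ["mould", "ct", "mri", "pet", "tp", "qa"]
        assert totals[app_cols].sum() == len(apps)

    def test_planted_per_group_counts_recovered_exactly(self):
        """The generator's ground-truth ledger equals the computed statistics."""
        result = generate_cohort(CohortSpec(n_patients=400), seed=5)
        refs, _ = clean_table(result.referrals)
        apps, _ = clean_table(result.appointments)
        fracs, _ = clean_table(result.fractions)
        rs = resource_stats(refs, apps, fracs, PoolingMap.identity(), top_n=10)

        led = result.ledger.copy()
        led["ct"] = led["ct_site1"] + led["ct_site2"]
        for _, row in led.iterrows():
            cell = rs.table.loc[(row["diagnosis"], row["intent"])]
            for col in ("patients", "mould", "ct", "mri", "pet", "tp", "qa", "fractions"):
                assert cell[col] == row[col], (row["diagnosis"], row["intent"], col)
        assert len(rs.table) == len(led)

    def test_report_frame_totals_equal_column_sums(self):
        result = generate_cohort(CohortSpec(n_patients=300), seed=3)
        refs, _ = clean_table(result.referrals)
        rs = resource_stats(substitute_intents(refs, "ratio"), [], [], top_n=5)
        frame = rs.to_frame()
        top = frame.iloc[:5]
        assert frame.loc[("TOTAL (5)", ""), "patients"] == top["patients"].sum()
        assert (
            frame.loc[("TOTAL ALL", ""), "patients"]
            == frame.loc[("TOTAL (5)", ""), "patients"] + frame.loc[("Other", ""), "patients"]
        )


class TestMonthlyInflow:
    def test_single_month_bucket(self):
        refs = [make_referral(i, day=3 + i) for i in range(5)]
        window = DateWindow(date(2015, 1, 1), date(2015, 3, 31))
        series = monthly_inflow(refs, window)
        assert len(series) == 3
        assert series[pd.Period("2015-01")] == 5
        assert series.sum() == 5

    def test_sixteen_month_window_gives_sixteen_buckets(self, cleaned_study_referrals):
        records, _ = cleaned_study_referrals
        series = monthly_inflow(records, DateWindow(date(2015, 1, 1), date(2016, 4, 30)))
        assert len(series) == 16
        assert series.sum() == len(records)

    def test_empty_input_is_all_zero(self):
        series = monthly_inflow([], DateWindow(date(2015, 1, 1), date(2015, 6, 30)))
        assert len(series) == 6 and series.sum() == 0


class TestExport:
    def test_bundle_round_trips_and_is_deterministic(self, tmp_path):
        result = generate_cohort(CohortSpec(n_patients=200), seed=9)
        refs, _ = clean_table(result.referrals)
        refs = substitute_intents(refs, "ratio")
        gt = group_by_diagnosis_intent(refs)
        rs = resource_stats(refs, [], [], top_n=5)
        inflow = monthly_inflow(refs)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        files1 = export_application_dataset(out1, gt, rs, inflow)
        export_application_dataset(out2, gt, rs, inflow)
        for f1 in files1:
            assert f1.read_bytes() == (out2 / f1.name).read_bytes()
        reloaded = load_resource_stats(out1 / "resource_stats_full.csv", top_n=5)
        pd.testing.assert_frame_equal(reloaded.table, rs.table)
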