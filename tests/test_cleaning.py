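import random
from datetime import date

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rtdet.cleaning import (
    DEFAULT_DUPLICATE_KEYS,
    RowClass,
    classify_row,
    clean_table,
    find_duplicates,
    format_percentage,
    render_cleaning_report,
)
from rtdet.io_model import DateWindow, RawTable, TableKind, write_table
from rtdet.synthetic import generate_exact_fixture


class TestClassifyRow:
    @pytest.mark.parametrize(
        "row,expected",
        [
            (("", "", "", ""), RowClass.BLANK_ROW),
            ((" ", "  ", "", " "), RowClass.BLANK_ROW),
            (("P1", "", "Curative", "2015-01-01"), RowClass.NULL_KEY_FIELD),
            (("P1", "ZZZ99@", "", "2015-01-01"), RowClass.IRRELEVANT),
            (("P1", "9C5", "", "2015-01-01"), RowClass.IRRELEVANT),
            (("P1", "C50", "C", "32/13/2015"), RowClass.IRRELEVANT),
            (("P1", "C50", "", "2015-01-01"), RowClass.VALID),  # missing intent kept
            (("P1", "C50.1", "Palliative", "2015-01-01"), RowClass.VALID),
        ],
    )
    def test_referral_classes_and_precedence(self, row, expected):
        assert classify_row(row, TableKind.REFERRAL) is expected

    @pytest.mark.parametrize(
        "row,expected",
        [
            (("A1", "P1", "", "2015-01-01"), RowClass.NULL_KEY_FIELD),
            (("", "P1", "mould", "2015-01-01"), RowClass.NULL_KEY_FIELD),
            (("A1", "P1", "laser", "2015-01-01"), RowClass.IRRELEVANT),
            (("A1", "P1", "mould", "corrupt"), RowClass.IRRELEVANT),
            (("A1", "P1", "CT-Site1", "2015-01-01"), RowClass.VALID),
        ],
    )
    def test_appointment_classes(self, row, expected):
        assert classify_row(row, TableKind.APPOINTMENT) is expected

    @pytest.mark.parametrize(
        "row,expected",
        [
            (("", "2015-01-01"), RowClass.NULL_KEY_FIELD),
            (("P1", "??"), RowClass.IRRELEVANT),
            (("P1", "2015-01-01"), RowClass.VALID),
        ],
    )
    def test_fraction_classes(self, row, expected):
        assert classify_row(row, TableKind.FRACTION) is expected


class TestFindDuplicates:
    def test_second_of_identical_pair_marked(self):
        rows = [("P1", "C50", "C", "2015-01-01"), ("P1", "C50", "C", "2015-01-01")]
        assert find_duplicates(
            rows, DEFAULT_DUPLICATE_KEYS[TableKind.REFERRAL], TableKind.REFERRAL
        ) == {1}

    def test_all_distinct_gives_empty_set(self):
        rows = [("P1", "C50", "C", "2015-01-01"), ("P2", "C50", "C", "2015-01-01")]
        assert (
            find_duplicates(
                rows, DEFAULT_DUPLICATE_KEYS[TableKind.REFERRAL], TableKind.REFERRAL
            )
            == set()
        )

    def test_appointment_identity_is_the_unique_id(self):
        rows = [
            ("A1", "P1", "qa", "2015-01-01"),
            ("A1", "P2", "qa", "2015-02-01"),  # same id, different content
            ("A2", "P1", "qa", "2015-01-01"),
        ]
        assert find_duplicates(rows, ("appointment_id",), TableKind.APPOINTMENT) == {1}


@pytest.mark.parametrize(
    "num,den,expected",
    [
        (304, 1285, "24"),
        (578, 3916, "15"),
        (28, 3916, "1"),
        (36, 1662, "2"),
        (66, 1662, "4"),
        (35, 1285, "3"),
        (4, 58228, "<1"),
        (0, 10, "0"),
        (1, 2, "50"),
        (1, 201, "<1"),  # 0.497 -> strictly positive but rounds to zero
        (1, 199, "1"),  # 0.503 -> half-up to 1
        (5, 0, "N/A"),
    ],
)
def test_format_percentage_rendering(num, den, expected):
    assert format_percentage(num, den) == expected


def _random_raw_referrals(rng, n):
    rows = []
    for _ in range(n):
        kind = rng.random()
        pid = f"P{rng.randrange(8)}"
        d = f"2015-0{rng.randrange(1, 9)}-1{rng.randrange(10)}"
        if kind < 0.08:
            rows.append(("", "", "", ""))
        elif kind < 0.18:
            rows.append((pid, "", "C", d))
        elif kind < 0.30:
            rows.append((pid, rng.choice(["##", "9X5", "C5"]), "", d))
        elif kind < 0.4:
            rows.append((pid, "C50", "C", "garbage-date"))
        else:
            rows.append((pid, rng.choice(["C50", "C61"]), rng.choice(["C", "P", ""]), d))
    return rows


class TestCleanTable:
    def test_brute_force_oracle_on_random_tables(self):
        """Removal accounting equals an independent quadratic scan."""
        rng = random.Random(42)
        for trial in range(20):
            rows = _random_raw_referrals(rng, rng.randrange(0, 200))
            raw = RawTable(TableKind.REFERRAL, tuple(rows), f"trial{trial}")
            records, stats = clean_table(raw)

            # oracle: classify each row, then quadratic duplicate scan on valid rows
            classes = [classify_row(r, TableKind.REFERRAL) for r in rows]
            valid = [r for r, c in zip(rows, classes) if c is RowClass.VALID]
            dup = sum(1 for i, r in enumerate(valid) if r in valid[:i])
            assert stats.duplicate_count == dup
            for cls in (RowClass.BLANK_ROW, RowClass.NULL_KEY_FIELD, RowClass.IRRELEVANT):
                assert stats.invalid_counts[cls] == sum(1 for c in classes if c is cls)
            assert stats.final_count == len(valid) - dup == len(records)

    def test_conservation_and_idempotence(self, study_fixture_tables):
        for raw in study_fixture_tables.values():
            records, stats = clean_table(raw)
            assert (
                stats.initial_count
                == stats.duplicate_count + stats.invalid_total + stats.final_count
            )
            # feeding the cleaned output back removes nothing
            import io

            buf = io.StringIO()
            write_table(records, buf, raw.table_kind)
            buf.seek(0)
            from rtdet.io_model import parse_raw_table

            records2, stats2 = clean_table(parse_raw_table(buf, raw.table_kind))
            assert stats2.duplicate_count == 0
            assert stats2.invalid_total == 0
            assert records2 == records

    def test_survivors_keep_source_order(self):
        rows = (
            ("P3", "C50", "C", "2015-03-01"),
            ("", "", "", ""),
            ("P1", "C50", "C", "2015-01-01"),
            ("P3", "C50", "C", "2015-03-01"),  # duplicate of first
            ("P2", "C61", "P", "2015-02-01"),
        )
        records, _ = clean_table(RawTable(TableKind.REFERRAL, rows, "t"))
        assert [r.patient_id for r in records] == ["P3", "P1", "P2"]

    def test_window_filter_runs_before_accounting(self):
        rows = (
            ("P1", "C50", "C", "2015-06-01"),
            ("P2", "C50", "C", "2016-05-01"),  # outside window
            ("", "", "", ""),
        )
        window = DateWindow(date(2015, 1, 1), date(2016, 4, 30))
        records, stats = clean_table(
            RawTable(TableKind.REFERRAL, rows, "t"), window=window
        )
        assert stats.windowed_out_count == 1
        assert stats.initial_count == 2
        assert stats.final_count == 1 == len(records)


class TestRenderCleaningReport:
    def test_report_row_per_table_with_rendered_percentages(self, study_fixture_tables):
        stats = [clean_table(raw)[1] for raw in study_fixture_tables.values()]
        report = render_cleaning_report(stats)
        assert list(report["table"]) == list(study_fixture_tables)
        qa = report.set_index("table").loc["qa"]
        assert (qa["initial"], qa["duplicates"], qa["duplicates_pct"]) == (1285, 304, "24")
        assert (qa["invalid_total"], qa["invalid_pct"], qa["final"]) == (35, "3", 946)

    def test_empty_table_renders_zero_row(self):
        _, stats = clean_table(RawTable(TableKind.FRACTION, (), "empty"))
        row = render_cleaning_report([stats]).iloc[0]
        assert row["initial"] == 0 and row["final"] == 0
        assert row["duplicates_pct"] == "N/A"  # zero denominator marker
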