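"""Row classification, deduplication and cleaning statistics.

Raw OIS exports mix valid rows with blank lines, rows whose key content field
is NULL, rows with corrupted content (malformed diagnosis codes, unparseable
dates) and exact duplicates.  ``clean_table`` removes them in a fixed order,
counting each removal exactly once, and returns the surviving typed records
together with a per-table :class:`CleaningStats` suitable for a
data-quality report.

Classification precedence (mutually exclusive): blank row, then NULL key
field, then irrelevant content, then valid.  Referrals with an empty *intent*
are deliberately retained as ``unknown`` — missing treatment intent is handled
downstream by substitution, not by removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .io_model import (
    CANONICAL_FIELDS,
    ICD10_CATEGORY_RE,
    ColumnMap,
    ConfigurationError,
    DateWindow,
    RawTable,
    Record,
    TableKind,
    _build_record,
    normalize_task,
    parse_date,
)

__all__ = [
    "RowClass",
    "CleaningStats",
    "DEFAULT_DUPLICATE_KEYS",
    "classify_row",
    "find_duplicates",
    "clean_table",
    "format_percentage",
    "render_cleaning_report",
    "round_half_up",
]


class RowClass(str, Enum):
    VALID = "valid"
    BLANK_ROW = "blank_row"
    NULL_KEY_FIELD = "null_key_field"
    IRRELEVANT = "irrelevant"


#: Canonical-field tuples defining row identity for duplicate removal.
#: Appointments are identified by their unique appointment id alone.
DEFAULT_DUPLICATE_KEYS: dict[TableKind, tuple[str, ...]] = {
    TableKind.REFERRAL: ("patient_id", "diagnosis", "intent", "referral_date"),
    TableKind.APPOINTMENT: ("appointment_id",),
    TableKind.FRACTION: ("patient_id", "fraction_date"),
}

_INVALID_CLASSES = (RowClass.BLANK_ROW, RowClass.NULL_KEY_FIELD, RowClass.IRRELEVANT)


def round_half_up(x: float) -> int:
    """Round half away from zero to the nearest integer (5.5 -> 6, -5.5 -> -6)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def format_percentage(numerator: int, denominator: int) -> str:
    """Render ``100 * numerator / denominator`` as an integer percentage string.

    Matches the report conventions: values that would round to zero but are
    strictly positive render ``"<1"``; an exact zero renders ``"0"``; a zero
    denominator renders the undefined-value marker ``"N/A"``.
    """
    if denominator == 0:
        return "N/A"
    if numerator == 0:
        return "0"
    p = 100.0 * numerator / denominator
    if 0 < p < 0.5:
        return "<1"
    return str(round_half_up(p))


def classify_row(
    raw_row: Sequence[str],
    table_kind: TableKind,
    column_map: ColumnMap | None = None,
) -> RowClass:
    """Classify a canonical-order raw row.

    blank_row
        every field empty or whitespace;
    null_key_field
        the table's key content field is empty — diagnosis for referrals,
        task or appointment id for appointments, patient id for fractions;
    irrelevant
        unrecognised format or corrupted content: diagnosis failing ICD-10
        category validation, unrecognised task token, or unparseable date;
    valid
        everything else.
    """
    cmap = column_map or ColumnMap.default()
    if all(not str(v).strip() for v in raw_row):
        return RowClass.BLANK_ROW
    if table_kind is TableKind.REFERRAL:
        patient_id, diagnosis, _intent, date_raw = raw_row
        if not diagnosis.strip():
            return RowClass.NULL_KEY_FIELD
        if not ICD10_CATEGORY_RE.match(diagnosis.strip()):
            return RowClass.IRRELEVANT
        if parse_date(date_raw, cmap.date_format) is None:
            return RowClass.IRRELEVANT
        return RowClass.VALID
    if table_kind is TableKind.APPOINTMENT:
        appointment_id, _patient_id, task_raw, date_raw = raw_row
        if not appointment_id.strip() or not task_raw.strip():
            return RowClass.NULL_KEY_FIELD
        if normalize_task(task_raw) is None:
            return RowClass.IRRELEVANT
        if parse_date(date_raw, cmap.date_format) is None:
            return RowClass.IRRELEVANT
        return RowClass.VALID
    if table_kind is TableKind.FRACTION:
        patient_id, date_raw = raw_row
        if not patient_id.strip():
            return RowClass.NULL_KEY_FIELD
        if parse_date(date_raw, cmap.date_format) is None:
            return RowClass.IRRELEVANT
        return RowClass.VALID
    raise ConfigurationError(f"unknown table kind {table_kind!r}")


def find_duplicates(
    rows: Sequence[Sequence[str]],
    key: tuple[str, ...],
    table_kind: TableKind,
) -> set[int]:
    """Indices of surplus rows under the identity key; first occurrence kept.

    ``rows`` are canonical-order raw rows (normally pre-classified valid);
    identity is the tuple of the key fields' trimmed values.
    """
    canon = CANONICAL_FIELDS[table_kind]
    missing = [f for f in key if f not in canon]
    if missing:
        raise ConfigurationError(f"duplicate key fields {missing} not on {table_kind.value}")
    idx = [canon.index(f) for f in key]
    seen: set[tuple[str, ...]] = set()
    surplus: set[int] = set()
    for i, row in enumerate(rows):
        k = tuple(str(row[j]).strip() for j in idx)
        if k in seen:
            surplus.add(i)
        else:
            seen.add(k)
    return surplus


@dataclass
class CleaningStats:
    """Per-table cleaning accounting (one report row).

    Conservation invariant: ``final_count = initial_count - duplicate_count -
    sum(invalid_counts.values())``.  ``windowed_out_count`` rows fell outside
    the requested date window and never entered the accounting.
    """

    table_kind: TableKind
    label: str
    initial_count: int
    duplicate_count: int
    invalid_counts: dict[RowClass, int]
    final_count: int
    windowed_out_count: int = 0

    def __post_init__(self) -> None:
        expected = self.initial_count - self.duplicate_count - self.invalid_total
        if expected != self.final_count:
            raise ValueError(
                f"cleaning stats not conserved for {self.label!r}: "
                f"{self.initial_count} - {self.duplicate_count} - "
                f"{self.invalid_total} != {self.final_count}"
            )

    @property
    def invalid_total(self) -> int:
        return sum(self.invalid_counts.values())

    @property
    def duplicate_pct(self) -> str:
        return format_percentage(self.duplicate_count, self.initial_count)

    @property
    def invalid_pct(self) -> str:
        return format_percentage(self.invalid_total, self.initial_count)


def clean_table(
    raw_table: RawTable,
    column_map: ColumnMap | None = None,
    window: DateWindow | None = None,
    duplicate_key: tuple[str, ...] | None = None,
    label: str | None = None,
) -> tuple[list[Record], CleaningStats]:
    """Window-filter, deduplicate and remove invalid rows from a raw table.

    Rows whose date parses but falls outside the window are dropped before any
    accounting.  Remaining rows are classified; duplicates are found among the
    valid rows only (all-but-first under the identity key).  Survivors are
    returned as typed records in source order.
    """
    cmap = column_map or ColumnMap.default()
    key = duplicate_key or DEFAULT_DUPLICATE_KEYS[raw_table.table_kind]
    date_field = CANONICAL_FIELDS[raw_table.table_kind][-1]
    date_idx = CANONICAL_FIELDS[raw_table.table_kind].index(date_field)

    windowed_out = 0
    kept_rows: list[tuple[str, ...]] = []
    for row in raw_table.rows:
        if window is not None:
            d = parse_date(row[date_idx], cmap.date_format)
            if d is not None and d not in window:
                windowed_out += 1
                continue
        kept_rows.append(row)

    classes = [classify_row(row, raw_table.table_kind, cmap) for row in kept_rows]
    valid_indices = [i for i, c in enumerate(classes) if c is RowClass.VALID]
    surplus_local = find_duplicates(
        [kept_rows[i] for i in valid_indices], key, raw_table.table_kind
    )
    surplus = {valid_indices[j] for j in surplus_local}

    invalid_counts = {c: 0 for c in _INVALID_CLASSES}
    for c in classes:
        if c is not RowClass.VALID:
            invalid_counts[c] += 1

    records: list[Record] = []
    for i in valid_indices:
        if i in surplus:
            continue
        rec = _build_record(raw_table.table_kind, kept_rows[i], cmap)
        if rec is None:  # classify_row and record validation must agree
            raise RuntimeError(f"row classified valid but failed typing: {kept_rows[i]}")
        records.append(rec)

    stats = CleaningStats(
        table_kind=raw_table.table_kind,
        label=label or raw_table.source_label or raw_table.table_kind.value,
        initial_count=len(kept_rows),
        duplicate_count=len(surplus),
        invalid_counts=invalid_counts,
        final_count=len(records),
        windowed_out_count=windowed_out,
    )
    return records, stats


def render_cleaning_report(stats: Sequence[CleaningStats]) -> pd.DataFrame:
    """Assemble per-table cleaning statistics into a report table.

    One row per cleaned table with raw counts, the per-class invalid
    breakdown, the combined invalid count, and rendered percentage columns
    (relative to the initial count).
    """
    rows = []
    for s in stats:
        rows.append(
            {
                "table": s.label,
                "kind": s.table_kind.value,
                "initial": s.initial_count,
                "duplicates": s.duplicate_count,
                "duplicates_pct": s.duplicate_pct,
                "null_key": s.invalid_counts.get(RowClass.NULL_KEY_FIELD, 0),
                "blank": s.invalid_counts.get(RowClass.BLANK_ROW, 0),
                "irrelevant": s.invalid_counts.get(RowClass.IRRELEVANT, 0),
                "invalid_total": s.invalid_total,
                "invalid_pct": s.invalid_pct,
                "final": s.final_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "table",
            "kind",
            "initial",
            "duplicates",
            "duplicates_pct",
            "null_key",
            "blank",
            "irrelevant",
            "invalid_total",
            "invalid_pct",
            "final",
        ],
    )
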