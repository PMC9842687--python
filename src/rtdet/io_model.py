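"""Parsing, normalisation and round-trip I/O for raw oncology-information-system tables.

Raw exports arrive as three delimiter-separated text tables — referrals,
appointments and fractions — whose column names and intent spellings vary
between installations.  A :class:`ColumnMap` binds the source schema to the
canonical fields used throughout the pipeline; parsing keeps every data line
verbatim (trimmed strings only, no validity judgement) so that the cleaning
stage can classify and count contamination faithfully.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import yaml

__all__ = [
    "TableKind",
    "Intent",
    "Task",
    "ColumnMap",
    "RawTable",
    "ReferralRecord",
    "AppointmentRecord",
    "FractionRecord",
    "DateWindow",
    "ConfigurationError",
    "CANONICAL_FIELDS",
    "ICD10_CATEGORY_RE",
    "parse_raw_table",
    "normalize_intent",
    "normalize_task",
    "parse_date",
    "filter_by_window",
    "write_table",
    "records_from_raw",
    "read_records",
]


class ConfigurationError(ValueError):
    """Raised when a column map or run configuration is inconsistent."""


class TableKind(str, Enum):
    REFERRAL = "referral"
    APPOINTMENT = "appointment"
    FRACTION = "fraction"


class Intent(str, Enum):
    CURATIVE = "curative"
    PALLIATIVE = "palliative"
    UNKNOWN = "unknown"


class Task(str, Enum):
    """Closed set of pre-treatment / planning tasks tracked per appointment."""

    MOULD = "mould"
    CT_SITE1 = "ct_site1"
    CT_SITE2 = "ct_site2"
    MRI = "mri"
    PET = "pet"
    QA = "qa"
    TP = "tp"


#: Canonical field order per table kind; parsing remaps source columns to this.
CANONICAL_FIELDS: dict[TableKind, tuple[str, ...]] = {
    TableKind.REFERRAL: ("patient_id", "diagnosis", "intent", "referral_date"),
    TableKind.APPOINTMENT: ("appointment_id", "patient_id", "task", "appointment_date"),
    TableKind.FRACTION: ("patient_id", "fraction_date"),
}

#: ICD-10 category pattern: one letter, two digits, optional dotted subcode.
ICD10_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$", re.IGNORECASE)

#: Default source-string -> canonical intent vocabulary (case-insensitive keys).
DEFAULT_INTENT_VOCABULARY: dict[str, str] = {
    "curative": "curative",
    "cur": "curative",
    "c": "curative",
    "palliative": "palliative",
    "pall": "palliative",
    "p": "palliative",
    "unknown": "unknown",
}

_TASK_ALIASES: dict[str, Task] = {
    "mould": Task.MOULD,
    "mold": Task.MOULD,
    "ct-site1": Task.CT_SITE1,
    "ct_site1": Task.CT_SITE1,
    "ctsite1": Task.CT_SITE1,
    "ct site1": Task.CT_SITE1,
    "ct1": Task.CT_SITE1,
    "ct-site2": Task.CT_SITE2,
    "ct_site2": Task.CT_SITE2,
    "ctsite2": Task.CT_SITE2,
    "ct site2": Task.CT_SITE2,
    "ct2": Task.CT_SITE2,
    "mri": Task.MRI,
    "mr": Task.MRI,
    "pet": Task.PET,
    "qa": Task.QA,
    "tp": Task.TP,
    "treatment plan": Task.TP,
}


@dataclass(frozen=True)
class ColumnMap:
    """Binding between a source export schema and canonical fields.

    Parameters
    ----------
    columns
        Per table kind, mapping *canonical field -> source column name*.
        Every canonical field of the table kind must be bound exactly once.
    intent_vocabulary
        Case-insensitive mapping of source intent spellings to the canonical
        intents (``curative`` / ``palliative`` / ``unknown``).
    date_format
        ``strptime`` pattern for all date fields.
    delimiter
        Field delimiter of the source files.
    """

    columns: Mapping[TableKind, Mapping[str, str]]
    intent_vocabulary: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INTENT_VOCABULARY)
    )
    date_format: str = "%Y-%m-%d"
    delimiter: str = ","

    def __post_init__(self) -> None:
        for kind, canon in CANONICAL_FIELDS.items():
            mapping = self.columns.get(kind)
            if mapping is None:
                raise ConfigurationError(f"column map missing table kind {kind.value!r}")
            missing = [f for f in canon if f not in mapping]
            if missing:
                raise ConfigurationError(
                    f"column map for {kind.value!r} missing canonical fields: {missing}"
                )
        allowed = {i.value for i in Intent}
        bad = {v for v in self.intent_vocabulary.values() if v not in allowed}
        if bad:
            raise ConfigurationError(f"intent vocabulary maps to non-canonical intents: {sorted(bad)}")

    @classmethod
    def default(cls) -> "ColumnMap":
        """Identity column map over the canonical field names."""
        return cls(columns={k: {f: f for f in v} for k, v in CANONICAL_FIELDS.items()})

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ColumnMap":
        """Load a column map from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"column map config {path} is not a mapping")
        columns = {
            TableKind(kind): dict(mapping)
            for kind, mapping in data.get("columns", {}).items()
        }
        kwargs: dict = {"columns": columns}
        if "intent_vocabulary" in data:
            kwargs["intent_vocabulary"] = {
                str(k): str(v) for k, v in data["intent_vocabulary"].items()
            }
        for key in ("date_format", "delimiter"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


@dataclass(frozen=True)
class RawTable:
    """An unjudged raw table: one string tuple per data line, in source order."""

    table_kind: TableKind
    rows: tuple[tuple[str, ...], ...]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ReferralRecord:
    """A patient's entry into the radiotherapy workflow."""

    patient_id: str
    diagnosis: str
    intent: Intent
    referral_date: date

    @property
    def event_date(self) -> date:
        return self.referral_date


@dataclass(frozen=True)
class AppointmentRecord:
    """A scheduled pre-treatment / planning task with a unique identifier."""

    appointment_id: str
    patient_id: str
    task: Task
    appointment_date: date

    @property
    def event_date(self) -> date:
        return self.appointment_date


@dataclass(frozen=True)
class FractionRecord:
    """One delivered radiotherapy fraction."""

    patient_id: str
    fraction_date: date

    @property
    def event_date(self) -> date:
        return self.fraction_date


@dataclass(frozen=True)
class DateWindow:
    """Inclusive calendar-date window used to scope an extraction."""

    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ConfigurationError(
                f"window start {self.start_date} after end {self.end_date}"
            )

    def __contains__(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date


def parse_date(value: str, date_format: str = "%Y-%m-%d") -> date | None:
    """Parse a date string under the configured format; ``None`` if unparseable."""
    try:
        return datetime.strptime(value.strip(), date_format).date()
    except (ValueError, TypeError):
        return None


def normalize_intent(raw_value: str, vocabulary: Mapping[str, str] | None = None) -> Intent:
    """Map a source intent spelling to a canonical intent.

    Lookup is case-insensitive on the whitespace-trimmed value; empty or
    unmapped strings map to :attr:`Intent.UNKNOWN`.  Total function.
    """
    vocab = DEFAULT_INTENT_VOCABULARY if vocabulary is None else vocabulary
    key = raw_value.strip().lower()
    if not key:
        return Intent.UNKNOWN
    folded = {str(k).strip().lower(): v for k, v in vocab.items()}
    return Intent(folded.get(key, "unknown"))


def normalize_task(raw_value: str) -> Task | None:
    """Map a source task spelling to the closed task set; ``None`` if unrecognised."""
    return _TASK_ALIASES.get(raw_value.strip().lower().replace("—", "-"))


def parse_raw_table(
    source: Union[str, Path, IO[str]],
    table_kind: TableKind,
    column_map: ColumnMap | None = None,
) -> RawTable:
    """Read a delimited text table and remap its columns to canonical order.

    Values are trimmed of surrounding whitespace but otherwise untouched; no
    validity judgement happens here.  Every data line yields exactly one row
    (short lines are padded with empty fields), so ``len(result)`` equals the
    number of data lines in the input.

    Raises
    ------
    ConfigurationError
        If a mapped source column is absent from the header.
    """
    cmap = column_map or ColumnMap.default()
    if hasattr(source, "read"):
        return _parse_stream(source, table_kind, cmap, source_label=getattr(source, "name", ""))
    path = Path(source)
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_stream(fh, table_kind, cmap, source_label=path.stem)


def _parse_stream(
    stream: IO[str], table_kind: TableKind, cmap: ColumnMap, source_label: str
) -> RawTable:
    reader = csv.reader(stream, delimiter=cmap.delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise ConfigurationError(f"{source_label or 'stream'}: no header row")
    header = [h.strip() for h in header]
    index: dict[str, int] = {}
    for canonical, source_col in cmap.columns[table_kind].items():
        if source_col not in header:
            raise ConfigurationError(
                f"{source_label or 'stream'}: mapped column {source_col!r} "
                f"(canonical {canonical!r}) not in header {header}"
            )
        index[canonical] = header.index(source_col)
    canon = CANONICAL_FIELDS[table_kind]
    rows = []
    for line in reader:
        padded = [v.strip() for v in line] + [""] * (len(header) - len(line))
        rows.append(tuple(padded[index[f]] if index[f] < len(padded) else "" for f in canon))
    return RawTable(table_kind=table_kind, rows=tuple(rows), source_label=source_label)


Record = Union[ReferralRecord, AppointmentRecord, FractionRecord]


def filter_by_window(records: Sequence[Record], window: DateWindow) -> list[Record]:
    """Keep exactly the records whose event date lies in the inclusive window."""
    return [r for r in records if r.event_date in window]


def _record_to_row(record: Record) -> tuple[str, ...]:
    if isinstance(record, ReferralRecord):
        return (
            record.patient_id,
            record.diagnosis,
            record.intent.value,
            record.referral_date.isoformat(),
        )
    if isinstance(record, AppointmentRecord):
        return (
            record.appointment_id,
            record.patient_id,
            record.task.value,
            record.appointment_date.isoformat(),
        )
    if isinstance(record, FractionRecord):
        return (record.patient_id, record.fraction_date.isoformat())
    raise TypeError(f"not a record: {record!r}")


def _kind_of(record: Record) -> TableKind:
    if isinstance(record, ReferralRecord):
        return TableKind.REFERRAL
    if isinstance(record, AppointmentRecord):
        return TableKind.APPOINTMENT
    return TableKind.FRACTION


def write_table(
    records: Sequence[Record],
    destination: Union[str, Path, IO[str]],
    table_kind: TableKind | None = None,
    delimiter: str = ",",
) -> None:
    """Write records as delimited text with the canonical header.

    Dates render ISO-8601; ``parse`` of the output followed by
    :func:`records_from_raw` yields identical records (round-trip).
    """
    if table_kind is None:
        if not records:
            raise ValueError("table_kind required when writing zero records")
        table_kind = _kind_of(records[0])
    rows = [_record_to_row(r) for r in records]

    def _write(fh: IO[str]) -> None:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CANONICAL_FIELDS[table_kind])
        writer.writerows(rows)

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(Path(destination), "w", newline="", encoding="utf-8") as fh:
            _write(fh)


def records_from_raw(raw: RawTable, column_map: ColumnMap | None = None) -> list[Record]:
    """Build typed records from a raw table, assuming every row is valid.

    Raises ``ValueError`` on the first invalid row — use the cleaning module
    when the input may be contaminated.
    """
    cmap = column_map or ColumnMap.default()
    out: list[Record] = []
    for i, row in enumerate(raw.rows):
        rec = _build_record(raw.table_kind, row, cmap)
        if rec is None:
            raise ValueError(f"row {i} of {raw.source_label or raw.table_kind.value} is not valid: {row}")
        out.append(rec)
    return out


def _build_record(kind: TableKind, row: tuple[str, ...], cmap: ColumnMap) -> Record | None:
    """Typed record from a canonical-order raw row, or ``None`` if invalid."""
    if kind is TableKind.REFERRAL:
        patient_id, diagnosis, intent_raw, date_raw = row
        d = parse_date(date_raw, cmap.date_format)
        if d is None or not ICD10_CATEGORY_RE.match(diagnosis):
            return None
        return ReferralRecord(
            patient_id=patient_id,
            diagnosis=diagnosis.upper(),
            intent=normalize_intent(intent_raw, cmap.intent_vocabulary),
            referral_date=d,
        )
    if kind is TableKind.APPOINTMENT:
        appointment_id, patient_id, task_raw, date_raw = row
        d = parse_date(date_raw, cmap.date_format)
        task = normalize_task(task_raw)
        if d is None or task is None or not appointment_id:
            return None
        return AppointmentRecord(
            appointment_id=appointment_id,
            patient_id=patient_id,
            task=task,
            appointment_date=d,
        )
    if kind is TableKind.FRACTION:
        patient_id, date_raw = row
        d = parse_date(date_raw, cmap.date_format)
        if d is None or not patient_id:
            return None
        return FractionRecord(patient_id=patient_id, fraction_date=d)
    raise ConfigurationError(f"unknown table kind {kind!r}")


def read_records(
    source: Union[str, Path, IO[str]],
    table_kind: TableKind,
    column_map: ColumnMap | None = None,
) -> list[Record]:
    """Parse a delimited file that is already clean into typed records."""
    return records_from_raw(parse_raw_table(source, table_kind, column_map), column_map)
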