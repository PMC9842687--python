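"""Synthetic raw OIS tables for testing and verification.

Real oncology-information-system exports cannot be shipped, so two seeded
generators stand in for them:

* **exact-marginal mode** — plants a prescribed number of clean rows, exact
  duplicates, NULL-key rows, blank rows and malformed ("irrelevant") rows,
  shuffled deterministically.  Cleaning such a fixture must recover the
  prescribed clean count exactly, which makes this mode the verification
  harness for the cleaning stage.  The default specs encode the study
  conditions of the 2015–16 department extraction (e.g. 3916 raw referrals =
  3310 clean + 28 duplicates + 103 NULL-diagnosis + 107 blank + 368
  malformed, with 2030 curative / 907 palliative / 373 unknown intents).

* **stochastic cohort mode** — draws a patient cohort with a configurable
  diagnosis mix, per-diagnosis curative share, intent missingness, per-task
  appointment rates, intent-dependent fraction counts and a seasonal monthly
  referral inflow, alongside a ground-truth ledger of per-group counts for
  parameter-recovery tests.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CANONICAL_FIELDS,
    ColumnMap,
    DateWindow,
    Intent,
    RawTable,
    TableKind,
    Task,
)

__all__ = [
    "ContaminationSpec",
    "CohortSpec",
    "CohortResult",
    "generate_exact_fixture",
    "generate_cohort",
    "study_contamination_specs",
    "write_raw_table",
]

#: Default extraction window: the 16-month period Jan 2015 – Apr 2016.
DEFAULT_WINDOW = DateWindow(date(2015, 1, 1), date(2016, 4, 30))

#: Monthly inflow weights (Jan..Dec): flat with a mild summer-vacation dip.
DEFAULT_MONTH_WEIGHTS = (1.0, 1.0, 1.0, 1.0, 1.0, 0.85, 0.7, 0.8, 1.0, 1.0, 1.0, 1.0)

#: Malformed diagnosis tokens used for "irrelevant" referral rows
#: (unrecognised format / corrupted content).
MALFORMED_DIAGNOSIS_POOL = (
    "ZZZ99@",
    "9C5",
    "C5",
    "##ERR",
    "X1234Z",
    "C5O.",
    "N/A?",
    "corrupt",
    "..",
    "C-50",
)

_BAD_DATE_POOL = ("32/13/2015", "not-a-date", "2015-00-00", "corrupt", "??")

#: Diagnosis pool (ICD-10 categories) with relative weights resembling a
#: large RT department's case mix: breast, prostate and lung dominate, with
#: secondary malignancies (C77/C79) mostly palliative.
DEFAULT_DIAGNOSIS_WEIGHTS: dict[str, float] = {
    "C50": 0.225,
    "C61": 0.125,
    "C34": 0.110,
    "C77": 0.065,
    "C79": 0.060,
    "C71": 0.030,
    "C90": 0.022,
    "C15": 0.020,
    "C54": 0.020,
    "C09": 0.018,
    "C20": 0.018,
    "C53": 0.016,
    "C01": 0.014,
    "C44": 0.013,
    "C83": 0.013,
    "C21": 0.012,
    "C49": 0.010,
    "C18": 0.020,
    "C67": 0.018,
    "C25": 0.015,
    "C16": 0.012,
    "C64": 0.012,
    "C32": 0.011,
    "C43": 0.011,
    "C56": 0.011,
    "C62": 0.009,
    "C73": 0.009,
    "C81": 0.009,
    "C82": 0.009,
    "C85": 0.009,
    "C41": 0.008,
    "C48": 0.008,
    "C11": 0.008,
    "C22": 0.008,
    "C80": 0.022,
}

#: Per-diagnosis curative share overrides (secondary malignancies and
#: myeloma are overwhelmingly palliative; breast/prostate mostly curative).
DEFAULT_CURATIVE_SHARE_OVERRIDES: dict[str, float] = {
    "C50": 0.95,
    "C61": 0.86,
    "C34": 0.55,
    "C77": 0.06,
    "C78": 0.05,
    "C79": 0.04,
    "C71": 0.30,
    "C90": 0.10,
    "C80": 0.15,
}

#: Mean appointments per patient by task (exercises every task incl. both CT
#: sites; TP slightly above one plan per patient, QA for a subset).
DEFAULT_APPOINTMENT_RATES: dict[Task, float] = {
    Task.MOULD: 0.47,
    Task.CT_SITE1: 0.95,
    Task.CT_SITE2: 0.15,
    Task.MRI: 0.20,
    Task.PET: 0.06,
    Task.TP: 1.18,
    Task.QA: 0.29,
}

#: Mean delivered fractions per patient by (true) intent: protracted
#: curative courses vs short palliative regimens.
DEFAULT_FRACTION_MEANS: dict[str, float] = {"curative": 22.0, "palliative": 8.0}


@dataclass(frozen=True)
class ContaminationSpec:
    """Exact-marginal recipe for one raw table.

    ``raw_total`` rows are emitted: ``clean_count`` valid rows plus the four
    contamination classes.  For referrals, ``intent_counts`` fixes how many
    clean rows are curative / palliative / unknown (blank intent).
    """

    table_kind: TableKind
    label: str
    clean_count: int
    duplicate_count: int = 0
    null_key_count: int = 0
    blank_count: int = 0
    irrelevant_count: int = 0
    task: Task | None = None
    intent_counts: tuple[int, int, int] | None = None
    window: DateWindow = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clean_count", "duplicate_count", "null_key_count", "blank_count", "irrelevant_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.table_kind is TableKind.APPOINTMENT and self.task is None:
            raise ValueError("appointment spec requires a task")
        if self.intent_counts is not None and sum(self.intent_counts) != self.clean_count:
            raise ValueError("intent_counts must sum to clean_count")

    @property
    def raw_total(self) -> int:
        return (
            self.clean_count
            + self.duplicate_count
            + self.null_key_count
            + self.blank_count
            + self.irrelevant_count
        )


def study_contamination_specs() -> dict[str, ContaminationSpec]:
    """The default exact-marginal fixture suite (2015–16 study conditions)."""
    return {
        "referrals": ContaminationSpec(
            table_kind=TableKind.REFERRAL,
            label="referrals",
            clean_count=3310,
            duplicate_count=28,
            null_key_count=103,
            blank_count=107,
            irrelevant_count=368,
            intent_counts=(2030, 907, 373),
        ),
        "mould": ContaminationSpec(
            table_kind=TableKind.APPOINTMENT,
            label="mould",
            task=Task.MOULD,
            clean_count=1560,
            duplicate_count=36,
            null_key_count=66,
        ),
        "ct_site1": ContaminationSpec(
            table_kind=TableKind.APPOINTMENT,
            label="ct_site1",
            task=Task.CT_SITE1,
            clean_count=3642,
            duplicate_count=41,
            null_key_count=52,
        ),
        "mri": ContaminationSpec(
            table_kind=TableKind.APPOINTMENT,
            label="mri",
            task=Task.MRI,
            clean_count=654,
            duplicate_count=13,
            null_key_count=17,
        ),
        "qa": ContaminationSpec(
            table_kind=TableKind.APPOINTMENT,
            label="qa",
            task=Task.QA,
            clean_count=946,
            duplicate_count=304,
            null_key_count=35,
        ),
        "fractions": ContaminationSpec(
            table_kind=TableKind.FRACTION,
            label="fractions",
            clean_count=58224,
            duplicate_count=0,
            null_key_count=4,
        ),
    }


def _month_starts(window: DateWindow) -> list[date]:
    months = []
    y, m = window.start_date.year, window.start_date.month
    while (y, m) <= (window.end_date.year, window.end_date.month):
        months.append(date(y, m, 1))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return months


def _draw_dates(
    rng: np.random.Generator,
    n: int,
    window: DateWindow,
    month_weights: Sequence[float] = DEFAULT_MONTH_WEIGHTS,
) -> list[date]:
    """Seeded dates inside the window, month chosen by seasonal weight."""
    months = _month_starts(window)
    w = np.array([month_weights[m.month - 1] for m in months], dtype=float)
    w /= w.sum()
    picks = rng.choice(len(months), size=n, p=w)
    out = []
    for k in picks:
        m = months[k]
        last = calendar.monthrange(m.year, m.month)[1]
        lo = window.start_date.day if m.replace(day=1) == window.start_date.replace(day=1) else 1
        hi = min(last, window.end_date.day) if (m.year, m.month) == (
            window.end_date.year,
            window.end_date.month,
        ) else last
        out.append(m.replace(day=int(rng.integers(lo, hi + 1))))
    return out


def _clean_referral_rows(
    spec: ContaminationSpec, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    codes = list(DEFAULT_DIAGNOSIS_WEIGHTS)
    probs = np.array(list(DEFAULT_DIAGNOSIS_WEIGHTS.values()), dtype=float)
    probs /= probs.sum()
    diagnoses = rng.choice(codes, size=spec.clean_count, p=probs)
    if spec.intent_counts is None:
        n_c = int(round(spec.clean_count * 0.613))
        n_p = int(round(spec.clean_count * 0.274))
        n_u = spec.clean_count - n_c - n_p
    else:
        n_c, n_p, n_u = spec.intent_counts
    intents = np.array(["Curative"] * n_c + ["Palliative"] * n_p + [""] * n_u)
    rng.shuffle(intents)
    dates = _draw_dates(rng, spec.clean_count, spec.window)
    return [
        (f"P{i + 1:05d}", str(diagnoses[i]), str(intents[i]), dates[i].isoformat())
        for i in range(spec.clean_count)
    ]


def _clean_appointment_rows(
    spec: ContaminationSpec, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    dates = _draw_dates(rng, spec.clean_count, spec.window)
    patients = rng.integers(1, 3311, size=spec.clean_count)
    return [
        (
            f"A{spec.task.value.upper()[:2]}{i + 1:06d}",
            f"P{patients[i]:05d}",
            spec.task.value,
            dates[i].isoformat(),
        )
        for i in range(spec.clean_count)
    ]


def _clean_fraction_rows(
    spec: ContaminationSpec, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    # one course of consecutive treatment days per patient, so every
    # (patient_id, date) identity key is unique among the clean rows
    rows: list[tuple[str, str]] = []
    pid = 0
    while len(rows) < spec.clean_count:
        pid += 1
        n_frac = int(rng.integers(5, 35))
        start = _draw_dates(rng, 1, spec.window)[0]
        for k in range(n_frac):
            d = start + timedelta(days=k)
            if d > spec.window.end_date:
                break
            rows.append((f"P{pid:05d}", d.isoformat()))
            if len(rows) == spec.clean_count:
                break
    return [tuple(r) for r in rows]


def _contaminated_rows(
    spec: ContaminationSpec, rng: np.random.Generator, clean: list[tuple[str, ...]]
) -> list[tuple[str, ...]]:
    n_fields = len(CANONICAL_FIELDS[spec.table_kind])
    rows: list[tuple[str, ...]] = []
    if spec.duplicate_count:
        picks = rng.integers(0, len(clean), size=spec.duplicate_count)
        rows.extend(clean[int(i)] for i in picks)
    for j in range(spec.null_key_count):
        d = _draw_dates(rng, 1, spec.window)[0].isoformat()
        if spec.table_kind is TableKind.REFERRAL:
            rows.append((f"PN{j + 1:05d}", "", "Curative" if rng.random() < 0.5 else "Palliative", d))
        elif spec.table_kind is TableKind.APPOINTMENT:
            rows.append((f"AN{j + 1:06d}", f"P{int(rng.integers(1, 3311)):05d}", "", d))
        else:
            rows.append(("", d))
    rows.extend((("",) * n_fields) for _ in range(spec.blank_count))
    for j in range(spec.irrelevant_count):
        d = _draw_dates(rng, 1, spec.window)[0].isoformat()
        if spec.table_kind is TableKind.REFERRAL:
            token = MALFORMED_DIAGNOSIS_POOL[j % len(MALFORMED_DIAGNOSIS_POOL)]
            rows.append((f"PX{j + 1:05d}", token, "", d))
        elif spec.table_kind is TableKind.APPOINTMENT:
            bad = _BAD_DATE_POOL[j % len(_BAD_DATE_POOL)]
            rows.append((f"AX{j + 1:06d}", f"P{int(rng.integers(1, 3311)):05d}", spec.task.value, bad))
        else:
            bad = _BAD_DATE_POOL[j % len(_BAD_DATE_POOL)]
            rows.append((f"PX{j + 1:05d}", bad))
    return rows


def generate_exact_fixture(spec: ContaminationSpec, seed: int | None = None) -> RawTable:
    """Emit a raw table with exactly the spec's contamination counts.

    Duplicates are exact copies of seeded-chosen clean rows; NULL-key rows
    are empty in the table's key content field only; blank rows are entirely
    empty; irrelevant rows carry an unrecognised diagnosis token or an
    unparseable date.  Rows are shuffled deterministically by the seed, so
    identical specs and seeds give identical tables.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.table_kind is TableKind.REFERRAL:
        clean = _clean_referral_rows(spec, rng)
    elif spec.table_kind is TableKind.APPOINTMENT:
        clean = _clean_appointment_rows(spec, rng)
    else:
        clean = _clean_fraction_rows(spec, rng)
    rows = clean + _contaminated_rows(spec, rng, clean)
    order = rng.permutation(len(rows))
    shuffled = tuple(rows[int(i)] for i in order)
    return RawTable(table_kind=spec.table_kind, rows=shuffled, source_label=spec.label)


@dataclass(frozen=True)
class CohortSpec:
    """Stochastic cohort generation parameters.

    Defaults emulate the 2015–16 department conditions: ~3310 patients over
    a 16-month window, case mix per :data:`DEFAULT_DIAGNOSIS_WEIGHTS`, global
    curative share ~0.69 of known intents with per-diagnosis overrides,
    11.3 % intent missingness, per-task appointment rates and
    intent-dependent fraction counts near the observed per-patient averages,
    and a mild summer dip in monthly referral inflow.
    """

    n_patients: int = 3310
    diagnosis_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_WEIGHTS)
    )
    curative_share: float = 0.69
    curative_share_overrides: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CURATIVE_SHARE_OVERRIDES)
    )
    intent_missingness: float = 0.113
    appointment_rates: Mapping[Task, float] = field(
        default_factory=lambda: dict(DEFAULT_APPOINTMENT_RATES)
    )
    fraction_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_MEANS)
    )
    month_weights: Sequence[float] = DEFAULT_MONTH_WEIGHTS
    window: DateWindow = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0 <= self.intent_missingness <= 1:
            raise ValueError("intent_missingness must be in [0, 1]")
        if any(w < 0 for w in self.diagnosis_weights.values()):
            raise ValueError("diagnosis weights must be non-negative")


@dataclass(frozen=True)
class CohortResult:
    """Generated raw tables plus the ground-truth per-group ledger.

    ``ledger`` has one row per (diagnosis, observed intent) with the true
    patient, per-task appointment and fraction counts — exactly what a
    correct attribution must recover from the tables.
    """

    referrals: RawTable
    appointments: RawTable
    fractions: RawTable
    ledger: pd.DataFrame


_LEDGER_COLUMNS = [
    "diagnosis",
    "intent",
    "patients",
    "mould",
    "ct_site1",
    "ct_site2",
    "mri",
    "pet",
    "tp",
    "qa",
    "fractions",
]


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortResult:
    """Draw a synthetic patient cohort with appointments and fractions.

    Per patient: a diagnosis from the case-mix weights; a true intent from
    the diagnosis's curative share; an observed intent blanked with the
    missingness probability; a referral date from the seasonal inflow;
    Poisson appointment counts per task (dated after the referral, clipped
    to the window); and a Poisson fraction count whose mean depends on the
    *true* intent.  The ledger records ground truth by observed group.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.n_patients == 0:
        empty = pd.DataFrame(columns=_LEDGER_COLUMNS)
        return CohortResult(
            referrals=RawTable(TableKind.REFERRAL, (), "referrals"),
            appointments=RawTable(TableKind.APPOINTMENT, (), "appointments"),
            fractions=RawTable(TableKind.FRACTION, (), "fractions"),
            ledger=empty,
        )

    codes = list(spec.diagnosis_weights)
    probs = np.array(list(spec.diagnosis_weights.values()), dtype=float)
    probs /= probs.sum()
    diagnoses = rng.choice(codes, size=spec.n_patients, p=probs)
    ref_dates = _draw_dates(rng, spec.n_patients, spec.window, spec.month_weights)

    referral_rows: list[tuple[str, ...]] = []
    appointment_rows: list[tuple[str, ...]] = []
    fraction_rows: list[tuple[str, ...]] = []
    ledger: dict[tuple[str, str], dict[str, int]] = {}
    appt_seq = 0

    for i in range(spec.n_patients):
        pid = f"P{i + 1:05d}"
        diag = str(diagnoses[i])
        p_cur = spec.curative_share_overrides.get(diag, spec.curative_share)
        true_intent = "curative" if rng.random() < p_cur else "palliative"
        missing = rng.random() < spec.intent_missingness
        observed = "unknown" if missing else true_intent
        ref_date = ref_dates[i]
        referral_rows.append((pid, diag, "" if missing else true_intent, ref_date.isoformat()))

        cell = ledger.setdefault(
            (diag, observed), {c: 0 for c in _LEDGER_COLUMNS[2:]}
        )
        cell["patients"] += 1

        for task, rate in spec.appointment_rates.items():
            n_app = int(rng.poisson(rate))
            for _ in range(n_app):
                appt_seq += 1
                d = min(
                    ref_date + timedelta(days=int(rng.integers(0, 45))),
                    spec.window.end_date,
                )
                appointment_rows.append(
                    (f"A{appt_seq:07d}", pid, task.value, d.isoformat())
                )
                cell[task.value] += 1

        # one fraction per treatment day starting ~30 days after referral;
        # courses may straddle the window end, as real courses do
        mean_frac = spec.fraction_means[true_intent]
        n_frac = int(rng.poisson(mean_frac))
        for k in range(n_frac):
            d = ref_date + timedelta(days=30 + k)
            fraction_rows.append((pid, d.isoformat()))
            cell["fractions"] += 1

    ledger_df = pd.DataFrame(
        [
            {"diagnosis": d, "intent": intent, **counts}
            for (d, intent), counts in sorted(ledger.items())
        ],
        columns=_LEDGER_COLUMNS,
    )
    return CohortResult(
        referrals=RawTable(TableKind.REFERRAL, tuple(referral_rows), "referrals"),
        appointments=RawTable(TableKind.APPOINTMENT, tuple(appointment_rows), "appointments"),
        fractions=RawTable(TableKind.FRACTION, tuple(fraction_rows), "fractions"),
        ledger=ledger_df,
    )


def write_raw_table(
    raw: RawTable, destination: str | Path, delimiter: str = ","
) -> Path:
    """Write a raw table with the canonical header (verbatim fields)."""
    import csv

    path = Path(destination)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CANONICAL_FIELDS[raw.table_kind])
        writer.writerows(raw.rows)
    return path
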