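"""Diagnosis-intent group tables, resource statistics and referral inflow.

The downstream application (a discrete-event simulation of the radiotherapy
workflow) consumes the cleaned cohort structured into diagnosis-intent
groups: the (pooled ICD-10 category, treatment intent) strata, ranked by
patient count, with per-group counts of preparatory appointments (mould, CT,
MRI, PET, treatment plans, QA) and delivered fractions.  The largest 20
groups typically cover about 80 % of patients; everything else is pooled
into an "Other" row.

A patient with several in-window referrals is attributed to the diagnosis
and intent of their earliest referral; their appointments and fractions
follow the patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cleaning import round_half_up
from .io_model import (
    AppointmentRecord,
    DateWindow,
    FractionRecord,
    Intent,
    ReferralRecord,
    Task,
)

__all__ = [
    "PoolingMap",
    "GroupTable",
    "GroupResourceStats",
    "RESOURCE_COLUMNS",
    "OTHER_LABEL",
    "group_by_diagnosis_intent",
    "top_coverage",
    "resource_stats",
    "monthly_inflow",
    "export_application_dataset",
    "load_resource_stats",
]

#: Resource columns of a group statistics table, in report order.
RESOURCE_COLUMNS = ["patients", "mould", "ct", "mri", "pet", "tp", "qa", "fractions"]

_TASK_TO_COLUMN = {
    Task.MOULD: "mould",
    Task.CT_SITE1: "ct",
    Task.CT_SITE2: "ct",
    Task.MRI: "mri",
    Task.PET: "pet",
    Task.QA: "qa",
    Task.TP: "tp",
}

OTHER_LABEL = ("Other", "")


@dataclass(frozen=True)
class PoolingMap:
    """Mapping from ICD-10 category codes to group labels.

    Defaults to identity except that the metastasis categories C77, C78 and
    C79 are merged into a single "C77-79" group, the convention used when the
    three secondary-malignancy codes are reported together.  Codes with
    subcodes are pooled on their three-character category.
    """

    overrides: Mapping[str, str] = field(
        default_factory=lambda: {"C77": "C77-79", "C78": "C77-79", "C79": "C77-79"}
    )

    @classmethod
    def identity(cls) -> "PoolingMap":
        return cls(overrides={})

    def pool(self, diagnosis: str) -> str:
        category = diagnosis.strip().upper()[:3]
        return self.overrides.get(category, category)

    def __call__(self, diagnosis: str) -> str:
        return self.pool(diagnosis)


@dataclass(frozen=True)
class GroupTable:
    """Ranked diagnosis-intent groups with patient counts and percentages.

    ``rows`` columns: group, intent, patients, pct (integer share of
    ``total_patients``, half-up).  Sorted by descending patient count, ties
    broken lexicographically by (group, intent).
    """

    rows: pd.DataFrame
    total_patients: int


def _patient_assignments(
    referrals: Sequence[ReferralRecord], pooling: PoolingMap
) -> dict[str, tuple[str, str]]:
    """Patient id -> (group, intent) of the earliest referral (source order on ties)."""
    best: dict[str, tuple] = {}
    for i, r in enumerate(referrals):
        key = (r.referral_date, i)
        if r.patient_id not in best or key < best[r.patient_id][0]:
            best[r.patient_id] = (key, (pooling.pool(r.diagnosis), r.intent.value))
    return {pid: grp for pid, (_, grp) in best.items()}


def group_by_diagnosis_intent(
    referrals: Sequence[ReferralRecord], pooling: PoolingMap | None = None
) -> GroupTable:
    """Build the ranked diagnosis-intent group table from substituted referrals.

    Each patient is counted once, in the group of their earliest referral.
    """
    pooling = pooling or PoolingMap()
    assignments = _patient_assignments(referrals, pooling)
    counts: dict[tuple[str, str], int] = {}
    for grp in assignments.values():
        counts[grp] = counts.get(grp, 0) + 1
    total = len(assignments)
    rows = pd.DataFrame(
        [
            {"group": g, "intent": intent, "patients": n}
            for (g, intent), n in counts.items()
        ],
        columns=["group", "intent", "patients"],
    )
    if not rows.empty:
        rows = rows.sort_values(
            by=["patients", "group", "intent"], ascending=[False, True, True]
        ).reset_index(drop=True)
        rows["pct"] = [round_half_up(100.0 * n / total) for n in rows["patients"]]
    else:
        rows["pct"] = pd.Series(dtype=int)
    return GroupTable(rows=rows, total_patients=total)


def top_coverage(group_table: GroupTable, n: int) -> tuple[pd.DataFrame, int, int | None]:
    """First ``n`` groups, their patient sum, and the share of all patients.

    Returns ``(top_rows, top_sum, coverage_pct)``; coverage is the half-up
    integer percentage of ``total_patients`` (``None`` for an empty cohort).
    """
    top = group_table.rows.head(n).copy()
    top_sum = int(top["patients"].sum())
    if group_table.total_patients == 0:
        return top, top_sum, None
    return top, top_sum, round_half_up(100.0 * top_sum / group_table.total_patients)


@dataclass(frozen=True)
class GroupResourceStats:
    """Per-group resource counts over every diagnosis-intent group.

    ``table`` is indexed by (group, intent) and holds the columns of
    :data:`RESOURCE_COLUMNS`; orphan appointments/fractions (patient without
    a matching referral) sit under the ``("Other", "")`` index.  Report views
    (top-N rows, pooled Other, totals) are derived, so no count is ever lost
    between views.
    """

    table: pd.DataFrame
    top_n: int = 20

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, str], Mapping[str, int]], top_n: int = 20
    ) -> "GroupResourceStats":
        """Build from explicit per-group counts (missing columns filled with 0)."""
        df = pd.DataFrame.from_dict(counts, orient="index")
        for col in RESOURCE_COLUMNS:
            if col not in df.columns:
                df[col] = 0
        df = df[RESOURCE_COLUMNS].fillna(0).astype(int)
        df.index = pd.MultiIndex.from_tuples(df.index, names=["group", "intent"])
        return cls(table=df, top_n=top_n)

    def _ranked(self) -> pd.DataFrame:
        df = self.table
        named = df[[g != OTHER_LABEL[0] for g, _ in df.index]]
        order = named.assign(_g=[g for g, _ in named.index], _i=[i for _, i in named.index])
        order = order.sort_values(by=["patients", "_g", "_i"], ascending=[False, True, True])
        return order[RESOURCE_COLUMNS]

    def top_rows(self) -> pd.DataFrame:
        return self._ranked().head(self.top_n)

    def other_row(self) -> pd.Series:
        top_idx = set(self.top_rows().index)
        rest = self.table[[idx not in top_idx for idx in self.table.index]]
        return rest[RESOURCE_COLUMNS].sum().astype(int)

    def totals(self) -> pd.Series:
        return self.table[RESOURCE_COLUMNS].sum().astype(int)

    def to_frame(self) -> pd.DataFrame:
        """Report-shaped table: top-N rows, TOTAL (top), Other, TOTAL ALL."""
        top = self.top_rows()
        out = top.copy()
        out.loc[(f"TOTAL ({len(top)})", ""), :] = top.sum()
        out.loc[OTHER_LABEL, :] = self.other_row()
        out.loc[("TOTAL ALL", ""), :] = self.totals()
        return out.astype(int)


def resource_stats(
    referrals: Sequence[ReferralRecord],
    appointments: Sequence[AppointmentRecord],
    fractions: Sequence[FractionRecord],
    pooling: PoolingMap | None = None,
    top_n: int = 20,
) -> GroupResourceStats:
    """Attribute appointments and fractions to diagnosis-intent groups.

    Every cleaned appointment and fraction lands in exactly one cell: the
    group of its patient's earliest referral, or the orphan "Other" row when
    the patient has no in-window referral.  CT pools both CT sites.
    """
    pooling = pooling or PoolingMap()
    assignments = _patient_assignments(referrals, pooling)

    cells: dict[tuple[str, str], dict[str, int]] = {}

    def cell(group_key: tuple[str, str]) -> dict[str, int]:
        return cells.setdefault(group_key, {c: 0 for c in RESOURCE_COLUMNS})

    for grp in assignments.values():
        cell(grp)["patients"] += 1
    for a in appointments:
        grp = assignments.get(a.patient_id, OTHER_LABEL)
        cell(grp)[_TASK_TO_COLUMN[a.task]] += 1
    for f in fractions:
        grp = assignments.get(f.patient_id, OTHER_LABEL)
        cell(grp)["fractions"] += 1

    if not cells:
        df = pd.DataFrame(columns=RESOURCE_COLUMNS)
        df.index = pd.MultiIndex.from_tuples([], names=["group", "intent"])
        return GroupResourceStats(table=df.astype(int), top_n=top_n)
    return GroupResourceStats.from_counts(cells, top_n=top_n)


def monthly_inflow(
    referrals: Sequence[ReferralRecord], window: DateWindow | None = None
) -> pd.Series:
    """Referral counts bucketed by calendar month, zero-filled over the window.

    Returns a Series with a monthly ``PeriodIndex``; the sum of counts equals
    the number of referrals (window defaults to the data's own span).
    """
    dates = pd.to_datetime([r.referral_date for r in referrals])
    if window is not None:
        start = pd.Period(window.start_date, freq="M")
        end = pd.Period(window.end_date, freq="M")
    elif len(dates) > 0:
        start = pd.Period(dates.min(), freq="M")
        end = pd.Period(dates.max(), freq="M")
    else:
        return pd.Series(dtype=int, name="referrals")
    index = pd.period_range(start, end, freq="M")
    if len(dates) == 0:
        return pd.Series(0, index=index, name="referrals")
    counts = pd.Series(1, index=dates.to_period("M")).groupby(level=0).sum()
    return counts.reindex(index, fill_value=0).astype(int).rename("referrals")


def export_application_dataset(
    destination: str | Path,
    group_table: GroupTable,
    resources: GroupResourceStats,
    inflow: pd.Series,
    xlsx: bool = False,
) -> list[Path]:
    """Write the application-ready statistics bundle.

    Emits ``group_table.csv``, ``resource_stats.csv`` and
    ``monthly_inflow.csv`` under ``destination`` (plus an optional
    ``statistics.xlsx`` workbook with one sheet each).  Output is
    deterministic: identical inputs give byte-identical files.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    gt_path = dest / "group_table.csv"
    group_table.rows.to_csv(gt_path, index=False)
    written.append(gt_path)

    rs = resources.to_frame().reset_index()
    rs_path = dest / "resource_stats.csv"
    rs.to_csv(rs_path, index=False)
    written.append(rs_path)

    # full per-group table (no pooled/total rows) so a bundle can be reloaded
    # losslessly, e.g. as the reference side of a comparison
    full = resources.table.reset_index()
    full_path = dest / "resource_stats_full.csv"
    full.to_csv(full_path, index=False)
    written.append(full_path)

    inflow_df = pd.DataFrame(
        {
            "year": [p.year for p in inflow.index],
            "month": [p.month for p in inflow.index],
            "referrals": inflow.values,
        }
    )
    in_path = dest / "monthly_inflow.csv"
    inflow_df.to_csv(in_path, index=False)
    written.append(in_path)

    if xlsx:
        xlsx_path = dest / "statistics.xlsx"
        with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
            group_table.rows.to_excel(writer, sheet_name="groups", index=False)
            rs.to_excel(writer, sheet_name="resources", index=False)
            inflow_df.to_excel(writer, sheet_name="inflow", index=False)
        written.append(xlsx_path)
    return written


def load_resource_stats(path: str | Path, top_n: int = 20) -> GroupResourceStats:
    """Reload a ``resource_stats_full.csv`` written by the export step."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"group": str, "intent": str})
    for col in RESOURCE_COLUMNS:
        if col not in df.columns:
            df[col] = 0
    df = df.set_index(["group", "intent"])[RESOURCE_COLUMNS].astype(int)
    return GroupResourceStats(table=df, top_n=top_n)
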