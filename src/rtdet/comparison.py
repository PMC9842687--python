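"""Reference-vs-tool dataset comparison reports.

Verification of an automated cleaning run against a manually cleaned
reference dataset: per diagnosis-intent group and per resource variable, the
raw counts of both sides, their difference, the integer percent difference
(undefined when the reference count is zero), and — per variable — the
median absolute percent difference over the reference's largest N groups.
Medians are computed from the unrounded ratios, never from pre-rounded
cells.
"""

from __future__ import annotations

import json
import statistics as _stats
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cleaning import round_half_up
from .statistics import OTHER_LABEL, RESOURCE_COLUMNS, GroupResourceStats

__all__ = [
    "ComparisonReport",
    "pct_diff",
    "median_abs_pct_diff",
    "compare_datasets",
]


def pct_diff(ref: int, det: int) -> int | None:
    """Integer percent difference ``100*(det-ref)/ref``, half-up; ``None`` if ref is 0."""
    if ref < 0 or det < 0:
        raise ValueError("counts must be non-negative")
    if ref == 0:
        return None
    return round_half_up(100.0 * (det - ref) / ref)


def median_abs_pct_diff(pairs: Iterable[tuple[int, int]]) -> int | None:
    """Median absolute percent difference over (ref, det) count pairs.

    Computed from the unrounded ratios ``|det-ref|/ref``; pairs with a zero
    reference count are excluded; an even number of entries takes the mean of
    the middle two.  Returns the half-up rounded integer, or ``None`` when no
    pair has a nonzero reference.
    """
    vals = [100.0 * abs(det - ref) / ref for ref, det in pairs if ref != 0]
    if not vals:
        return None
    return round_half_up(_stats.median(vals))


@dataclass(frozen=True)
class ComparisonReport:
    """Comparison of two group-resource tables over the reference's top groups.

    ``cells`` columns: group, intent, variable, ref, det, diff, pct_diff
    (one row per top group x variable; pct_diff is NA when ref == 0).
    ``other``/``totals_top``/``totals_all`` hold the pooled remainder, the
    top-N totals and the grand totals in the same shape.  ``medians`` maps
    each variable to the median absolute percent difference over the top
    groups.
    """

    cells: pd.DataFrame
    other: pd.DataFrame
    totals_top: pd.DataFrame
    totals_all: pd.DataFrame
    medians: dict[str, int | None]
    top_n: int

    def to_frame(self) -> pd.DataFrame:
        """Single long-format frame with Other / TOTAL rows appended."""
        extra = []
        for label, df in (
            (f"TOTAL ({self.top_n})", self.totals_top),
            (OTHER_LABEL[0], self.other),
            ("TOTAL ALL", self.totals_all),
        ):
            d = df.copy()
            d.insert(0, "intent", "")
            d.insert(0, "group", label)
            extra.append(d)
        return pd.concat([self.cells, *extra], ignore_index=True)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "top_n": self.top_n,
            "cells": self.cells.to_dict(orient="records"),
            "other": self.other.to_dict(orient="records"),
            "totals_top": self.totals_top.to_dict(orient="records"),
            "totals_all": self.totals_all.to_dict(orient="records"),
            "median_abs_pct_diff": self.medians,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _jsonable(x):
    try:
        import numpy as np

        if isinstance(x, np.integer):
            return int(x)
        if isinstance(x, np.floating):
            return float(x)
    except ImportError:  # pragma: no cover
        pass
    if pd.isna(x):
        return None
    raise TypeError(f"not JSON serialisable: {x!r}")


def _variable_rows(group: tuple[str, str], ref_row, det_row) -> list[dict]:
    rows = []
    for var in RESOURCE_COLUMNS:
        ref_v = int(ref_row.get(var, 0))
        det_v = int(det_row.get(var, 0))
        rows.append(
            {
                "group": group[0],
                "intent": group[1],
                "variable": var,
                "ref": ref_v,
                "det": det_v,
                "diff": det_v - ref_v,
                "pct_diff": pct_diff(ref_v, det_v),
            }
        )
    return rows


def compare_datasets(
    ref_stats: GroupResourceStats,
    det_stats: GroupResourceStats,
    top_n: int | None = None,
) -> ComparisonReport:
    """Full comparison report between a reference and a tool-cleaned dataset.

    The reference's largest ``top_n`` groups (by patients) define the
    per-group rows; groups present on only one side count as zero on the
    other.  "Other" pools everything outside the top groups, on each side.
    """
    n = top_n if top_n is not None else ref_stats.top_n
    ref_top = ref_stats.table.pipe(_ranked_by_patients).head(n)
    top_keys = list(ref_top.index)

    ref_all, det_all = ref_stats.table, det_stats.table
    cells: list[dict] = []
    for key in top_keys:
        ref_row = ref_all.loc[key] if key in ref_all.index else pd.Series(dtype=int)
        det_row = det_all.loc[key] if key in det_all.index else pd.Series(dtype=int)
        cells.extend(_variable_rows(key, ref_row, det_row))
    cells_df = pd.DataFrame(
        cells, columns=["group", "intent", "variable", "ref", "det", "diff", "pct_diff"]
    )
    cells_df["pct_diff"] = cells_df["pct_diff"].astype("Int64")  # NA where ref == 0

    medians: dict[str, int | None] = {}
    for var in RESOURCE_COLUMNS:
        sub = cells_df[cells_df["variable"] == var]
        medians[var] = median_abs_pct_diff(list(zip(sub["ref"], sub["det"])))

    def _sum_over(table: pd.DataFrame, keys: list, inside: bool) -> pd.Series:
        mask = [(idx in set(keys)) == inside for idx in table.index]
        return table[mask][RESOURCE_COLUMNS].sum().astype(int)

    def _diff_frame(ref_sum: pd.Series, det_sum: pd.Series) -> pd.DataFrame:
        rows = []
        for var in RESOURCE_COLUMNS:
            r, d = int(ref_sum.get(var, 0)), int(det_sum.get(var, 0))
            rows.append(
                {"variable": var, "ref": r, "det": d, "diff": d - r, "pct_diff": pct_diff(r, d)}
            )
        df = pd.DataFrame(rows)
        df["pct_diff"] = df["pct_diff"].astype("Int64")
        return df

    totals_top = _diff_frame(
        _sum_over(ref_all, top_keys, True), _sum_over(det_all, top_keys, True)
    )
    other = _diff_frame(
        _sum_over(ref_all, top_keys, False), _sum_over(det_all, top_keys, False)
    )
    totals_all = _diff_frame(
        ref_all[RESOURCE_COLUMNS].sum().astype(int),
        det_all[RESOURCE_COLUMNS].sum().astype(int),
    )
    return ComparisonReport(
        cells=cells_df,
        other=other,
        totals_top=totals_top,
        totals_all=totals_all,
        medians=medians,
        top_n=n,
    )


def _ranked_by_patients(table: pd.DataFrame) -> pd.DataFrame:
    named = table[[g != OTHER_LABEL[0] for g, _ in table.index]]
    order = named.assign(
        _g=[g for g, _ in named.index], _i=[i for _, i in named.index]
    ).sort_values(by=["patients", "_g", "_i"], ascending=[False, True, True])
    return order[RESOURCE_COLUMNS]
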