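"""Substitution of missing treatment intent.

A fraction of cleaned referrals carries no usable treatment intent.  Rather
than discarding them, the pipeline assigns an intent per diagnosis under one
of four strategies: all curative, all palliative, an equal split, or the
known curative:palliative ratio of that diagnosis.  Integer allocation uses
deterministic largest-remainder apportionment (remainder ties to curative),
and within a diagnosis the individual unknowns are assigned in ascending
patient-id order, so identical inputs always produce identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .cleaning import round_half_up
from .io_model import Intent, ReferralRecord

__all__ = [
    "StrategyKind",
    "SubstitutionStrategy",
    "IntentShares",
    "ApportionmentUndefined",
    "intent_shares",
    "apportion_largest_remainder",
    "substitute_intents",
    "substitution_audit",
]


class ApportionmentUndefined(ValueError):
    """Both apportionment weights are zero; the caller must apply a fallback."""


class StrategyKind(str, Enum):
    ALL_CURATIVE = "all-curative"
    ALL_PALLIATIVE = "all-palliative"
    FIFTY_FIFTY = "fifty-fifty"
    RATIO = "ratio"


class FallbackPolicy(str, Enum):
    """What the ratio strategy does for a diagnosis with no known intents."""

    GLOBAL_RATIO = "global-ratio"
    FIFTY_FIFTY = "fifty-fifty"


@dataclass(frozen=True)
class SubstitutionStrategy:
    kind: StrategyKind
    fallback_policy: FallbackPolicy = FallbackPolicy.GLOBAL_RATIO

    @classmethod
    def parse(cls, name: str) -> "SubstitutionStrategy":
        return cls(kind=StrategyKind(name.strip().lower().replace("_", "-")))


@dataclass(frozen=True)
class IntentShares:
    """Known/unknown intent counts with rendered integer percentages.

    Curative and palliative shares are computed over the *known* referrals
    only; the unknown share is computed over the total.  Percentages are
    ``None`` when the respective denominator is zero.
    """

    known_curative: int
    known_palliative: int
    unknown: int

    @property
    def known_total(self) -> int:
        return self.known_curative + self.known_palliative

    @property
    def total(self) -> int:
        return self.known_total + self.unknown

    @property
    def curative_pct(self) -> int | None:
        if self.known_total == 0:
            return None
        return round_half_up(100.0 * self.known_curative / self.known_total)

    @property
    def palliative_pct(self) -> int | None:
        if self.known_total == 0:
            return None
        return round_half_up(100.0 * self.known_palliative / self.known_total)

    @property
    def unknown_pct(self) -> int | None:
        if self.total == 0:
            return None
        return round_half_up(100.0 * self.unknown / self.total)


def intent_shares(referrals: Sequence[ReferralRecord]) -> IntentShares:
    """Count referrals by intent."""
    c = sum(1 for r in referrals if r.intent is Intent.CURATIVE)
    p = sum(1 for r in referrals if r.intent is Intent.PALLIATIVE)
    u = sum(1 for r in referrals if r.intent is Intent.UNKNOWN)
    return IntentShares(known_curative=c, known_palliative=p, unknown=u)


def apportion_largest_remainder(
    unknown_count: int, weight_curative: float, weight_palliative: float
) -> tuple[int, int]:
    """Split ``unknown_count`` into curative/palliative integer shares.

    Largest-remainder apportionment over the two weights: each side gets the
    floor of its exact proportional share and the single leftover unit (if
    any) goes to the larger remainder, ties broken toward curative.  The
    result is within one unit of the exact proportion.

    Raises
    ------
    ApportionmentUndefined
        If both weights are zero (the caller's fallback policy applies).
    """
    if unknown_count < 0:
        raise ValueError("unknown_count must be non-negative")
    if weight_curative < 0 or weight_palliative < 0:
        raise ValueError("weights must be non-negative")
    total_w = weight_curative + weight_palliative
    if total_w == 0:
        raise ApportionmentUndefined("both apportionment weights are zero")
    exact_c = unknown_count * weight_curative / total_w
    exact_p = unknown_count * weight_palliative / total_w
    n_c, n_p = math.floor(exact_c), math.floor(exact_p)
    if n_c + n_p < unknown_count:  # one leftover unit at most with two parties
        if (exact_c - n_c) >= (exact_p - n_p):
            n_c += 1
        else:
            n_p += 1
    return n_c, n_p


def _diagnosis_allocation(
    strategy: SubstitutionStrategy,
    n_unknown: int,
    known_c: int,
    known_p: int,
    global_c: int,
    global_p: int,
) -> tuple[int, int]:
    if strategy.kind is StrategyKind.ALL_CURATIVE:
        return n_unknown, 0
    if strategy.kind is StrategyKind.ALL_PALLIATIVE:
        return 0, n_unknown
    if strategy.kind is StrategyKind.FIFTY_FIFTY:
        return apportion_largest_remainder(n_unknown, 1, 1)
    # ratio strategy
    try:
        return apportion_largest_remainder(n_unknown, known_c, known_p)
    except ApportionmentUndefined:
        if strategy.fallback_policy is FallbackPolicy.GLOBAL_RATIO:
            try:
                return apportion_largest_remainder(n_unknown, global_c, global_p)
            except ApportionmentUndefined:
                pass
        return apportion_largest_remainder(n_unknown, 1, 1)


def substitute_intents(
    referrals: Sequence[ReferralRecord],
    strategy: SubstitutionStrategy | StrategyKind | str,
) -> list[ReferralRecord]:
    """Replace every unknown intent; known intents and record order untouched.

    The 50-50 and ratio strategies apportion per diagnosis; which individual
    unknowns become curative is decided by ascending patient id within the
    diagnosis, making the whole operation deterministic.
    """
    if isinstance(strategy, str):
        strategy = SubstitutionStrategy.parse(strategy)
    elif isinstance(strategy, StrategyKind):
        strategy = SubstitutionStrategy(kind=strategy)

    global_c = sum(1 for r in referrals if r.intent is Intent.CURATIVE)
    global_p = sum(1 for r in referrals if r.intent is Intent.PALLIATIVE)

    unknowns_by_diag: dict[str, list[int]] = {}
    known_by_diag: dict[str, list[int]] = {}
    for i, r in enumerate(referrals):
        if r.intent is Intent.UNKNOWN:
            unknowns_by_diag.setdefault(r.diagnosis, []).append(i)

    assigned: dict[int, Intent] = {}
    for diag, indices in unknowns_by_diag.items():
        known_c = sum(
            1 for r in referrals if r.diagnosis == diag and r.intent is Intent.CURATIVE
        )
        known_p = sum(
            1 for r in referrals if r.diagnosis == diag and r.intent is Intent.PALLIATIVE
        )
        n_c, _n_p = _diagnosis_allocation(
            strategy, len(indices), known_c, known_p, global_c, global_p
        )
        # ascending patient_id decides which individuals become curative;
        # source index breaks patient-id ties for full determinism
        ordered = sorted(indices, key=lambda i: (referrals[i].patient_id, i))
        for rank, i in enumerate(ordered):
            assigned[i] = Intent.CURATIVE if rank < n_c else Intent.PALLIATIVE

    return [
        replace(r, intent=assigned[i]) if i in assigned else r
        for i, r in enumerate(referrals)
    ]


def substitution_audit(
    before: Sequence[ReferralRecord], after: Sequence[ReferralRecord]
) -> pd.DataFrame:
    """Per-diagnosis audit of what the substitution assigned.

    Columns: diagnosis, known curative/palliative counts, number of unknowns,
    and how many of those unknowns were assigned to each intent.
    """
    if len(before) != len(after):
        raise ValueError("before/after lists differ in length")
    rows: dict[str, dict[str, int]] = {}
    for b, a in zip(before, after):
        d = rows.setdefault(
            b.diagnosis,
            {
                "known_curative": 0,
                "known_palliative": 0,
                "unknown": 0,
                "assigned_curative": 0,
                "assigned_palliative": 0,
            },
        )
        if b.intent is Intent.CURATIVE:
            d["known_curative"] += 1
        elif b.intent is Intent.PALLIATIVE:
            d["known_palliative"] += 1
        else:
            d["unknown"] += 1
            if a.intent is Intent.CURATIVE:
                d["assigned_curative"] += 1
            elif a.intent is Intent.PALLIATIVE:
                d["assigned_palliative"] += 1
    df = pd.DataFrame(
        [{"diagnosis": k, **v} for k, v in sorted(rows.items())],
        columns=[
            "diagnosis",
            "known_curative",
            "known_palliative",
            "unknown",
            "assigned_curative",
            "assigned_palliative",
        ],
    )
    return df
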