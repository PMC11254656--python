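"""Pooled adverse-event incidences and chi-square comparison between groups.

Incidences are pooled by summing numerators and denominators over a group's
member arms, per category (any-grade TEAE, grade >= 3 TEAE, irAE, ...). Two
groups are compared per category with the Pearson chi-square test on the
pooled 2x2 table, df = 1, without continuity correction (pooled denominators
here are in the hundreds, where the uncorrected test is standard practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .datatypes import ValidationError
from .io import AECountRow
from .tables import GroupSpec

log = logging.getLogger(__name__)

__all__ = ["AEComparison", "pool_ae", "chisq_2x2", "compare_ae"]


@dataclass(frozen=True)
class AEComparison:
    category: str
    incidence_a: float
    incidence_b: float
    counts_a: tuple[int, int]  # (numerator, denominator)
    counts_b: tuple[int, int]
    chi2: float
    p: float


def pool_ae(rows: Sequence[AECountRow], group: GroupSpec) -> dict[str, tuple[int, int]]:
    """Pooled (numerator, denominator) per category over a group's member arms.

    A category reported by only some member arms is pooled over the arms that
    report it, with a warning.
    """
    members = set(group.member_arm_ids)
    mine = [r for r in rows if r.arm_id in members]
    if not mine:
        raise ValidationError(f"group {group.name}: no AE rows for any member arm")
    arms_seen = {r.arm_id for r in mine}
    out: dict[str, tuple[int, int]] = {}
    for cat in sorted({r.category for r in mine}):
        rows_cat = [r for r in mine if r.category == cat]
        reporting = {r.arm_id for r in rows_cat}
        if reporting != arms_seen:
            log.warning(
                "group %s: category %s reported by %d of %d member arms; "
                "pooling over available arms",
                group.name, cat, len(reporting), len(arms_seen),
            )
        out[cat] = (sum(r.numerator for r in rows_cat), sum(r.denominator for r in rows_cat))
    return out


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], df = 1, no correction."""
    if min(a, b, c, d) < 0:
        raise ValidationError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValidationError("chi-square undefined: zero margin")
    stat, p, _, _ = chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
    return float(stat), float(p)


def compare_ae(
    rows: Sequence[AECountRow], group_a: GroupSpec, group_b: GroupSpec
) -> list[AEComparison]:
    """Per-category chi-square comparisons of pooled incidences between two groups.

    Categories present on one side only are excluded with a warning.
    """
    pooled_a = pool_ae(rows, group_a)
    pooled_b = pool_ae(rows, group_b)
    shared = sorted(set(pooled_a) & set(pooled_b))
    for cat in sorted(set(pooled_a) ^ set(pooled_b)):
        log.warning("category %s present on one side only; excluded", cat)
    out = []
    for cat in shared:
        xa, na = pooled_a[cat]
        xb, nb = pooled_b[cat]
        stat, p = chisq_2x2(xa, na - xa, xb, nb - xb)
        out.append(
            AEComparison(
                category=cat,
                incidence_a=xa / na,
                incidence_b=xb / nb,
                counts_a=(xa, na),
                counts_b=(xb, nb),
                chi2=stat,
                p=p,
            )
        )
    return out
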