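"""Genomic abundance as a relative-age proxy.

Traits of ancient origin have had more time to duplicate and accumulate in
genomes, so the total copy count of a Venn group's traits within an
organism indexes the group's relative age.  This module computes
per-organism, per-group abundance totals and summarises them per
(group, superkingdom) panel on a log10(x+1) scale with Tukey 1.5xIQR
outliers and named extreme organisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import OrganismRecord, TraitMatrix, records_by_id
from .venn import VENN_GROUPS, VennAssignment

__all__ = [
    "GroupAbundanceProfile",
    "AbundanceSummary",
    "group_abundance",
    "group_abundance_table",
    "summarize_abundance",
]


@dataclass(frozen=True)
class GroupAbundanceProfile:
    """One organism's total abundance per Venn group."""

    organism_id: str
    superkingdom: str
    per_group_abundance: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_group_abundance.values())


@dataclass(frozen=True)
class AbundanceSummary:
    """Five-number summary of one (group, superkingdom) panel, log scale."""

    group: str
    superkingdom: str
    n_organisms: int
    five_number: tuple[float, float, float, float, float]  # min,q1,med,q3,max
    outliers: tuple[str, ...]
    argmax_id: str
    argmin_id: str

    def __post_init__(self) -> None:
        lo, q1, med, q3, hi = self.five_number
        if not (lo <= q1 <= med <= q3 <= hi):
            raise ValidationError("five-number summary out of order")


def group_abundance_table(
    matrix: TraitMatrix, assignments: Sequence[VennAssignment]
) -> pd.DataFrame:
    """Organisms x 7 Venn groups table of abundance totals."""
    group_of = pd.Series({a.trait_id: a.group for a in assignments})
    missing = [t for t in matrix.trait_ids if t not in group_of.index]
    if missing:
        raise ValidationError(f"traits lacking a Venn assignment: {missing[:10]}")
    table = (
        matrix.abundance.groupby(group_of.reindex(matrix.trait_ids).to_numpy())
        .sum()
        .T.reindex(columns=list(VENN_GROUPS), fill_value=0)
        .astype(np.int64)
    )
    table.index.name = "organism_id"
    return table


def group_abundance(
    matrix: TraitMatrix,
    assignments: Sequence[VennAssignment],
    metadata: Sequence[OrganismRecord],
) -> list[GroupAbundanceProfile]:
    """Per-organism abundance totals by Venn group.

    The seven group totals of each organism always sum to the organism's
    column total in the matrix (conservation identity, asserted here).
    """
    table = group_abundance_table(matrix, assignments)
    by_id = records_by_id(metadata)
    column_totals = matrix.abundance.sum(axis=0)
    profiles = []
    for org in matrix.organism_ids:
        row = table.loc[org]
        per_group = {g: int(row[g]) for g in VENN_GROUPS}
        assert sum(per_group.values()) == int(column_totals[org]), (
            f"abundance conservation violated for organism {org}"
        )
        profiles.append(
            GroupAbundanceProfile(
                organism_id=org,
                superkingdom=by_id[org].superkingdom,
                per_group_abundance=per_group,
            )
        )
    return profiles


def summarize_abundance(
    profiles: Sequence[GroupAbundanceProfile], group: str, superkingdom: str
) -> AbundanceSummary | None:
    """Log-scale five-number summary of one panel.

    Totals are transformed as log10(x+1) so organisms with zero abundance in
    a group stay in the panel.  Outliers follow the Tukey 1.5xIQR whisker
    rule; extremes are resolved deterministically (ties broken by organism
    id).  Returns ``None`` for an empty panel.
    """
    rows = [
        (p.organism_id, p.per_group_abundance.get(group, 0))
        for p in profiles
        if p.superkingdom == superkingdom
    ]
    if not rows:
        return None
    ids = [r[0] for r in rows]
    logs = np.array([math.log10(r[1] + 1) for r in rows])
    lo, q1, med, q3, hi = np.percentile(logs, [0, 25, 50, 75, 100], method="linear")
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(
        sorted(i for i, v in zip(ids, logs) if v < lower or v > upper)
    )
    argmin_id = ids[sorted(range(len(ids)), key=lambda k: (logs[k], ids[k]))[0]]
    argmax_id = ids[sorted(range(len(ids)), key=lambda k: (-logs[k], ids[k]))[0]]
    return AbundanceSummary(
        group=group,
        superkingdom=superkingdom,
        n_organisms=len(rows),
        five_number=(float(lo), float(q1), float(med), float(q3), float(hi)),
        outliers=outliers,
        argmax_id=argmax_id,
        argmin_id=argmin_id,
    )
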