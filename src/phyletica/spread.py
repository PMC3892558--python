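"""Spread (f-value) analysis.

The f-value of a trait in a superkingdom is the fraction of that
superkingdom's organisms carrying the trait: the number of proteomes or
functionomes harbouring it divided by the superkingdom's organism count.
It runs from 0 (absent) to 1 (omnipresent).  High, balanced f-distributions
across superkingdoms are read as vertical inheritance from a common
ancestor; low or strongly biased distributions as horizontal flux or
differential loss.

A trait's f-values are reported only for the superkingdoms named in its
Venn group label (where they are necessarily > 0); the denominator is always
the full organism count of the superkingdom.

The module also extracts the universal core (traits present in every
retained organism) and the near-universal cohort (overall f strictly above a
threshold, default 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import SUPERKINGDOMS, OrganismRecord, TraitMatrix
from .venn import VennAssignment, organisms_by_superkingdom

__all__ = [
    "SpreadProfile",
    "SpreadSummary",
    "f_value",
    "spread_profiles",
    "summarize_spread",
    "universal_core",
    "near_universal",
]


@dataclass(frozen=True)
class SpreadProfile:
    """Per-superkingdom f-values of one trait (full precision)."""

    trait_id: str
    venn_group: str
    f_by_superkingdom: Mapping[str, float]

    def __post_init__(self) -> None:
        for sk, f in self.f_by_superkingdom.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"trait {self.trait_id}: f_{sk}={f} outside [0,1]")
            if sk in self.venn_group and f <= 0.0:
                raise ValidationError(
                    f"trait {self.trait_id}: f_{sk}=0 contradicts group {self.venn_group}"
                )


@dataclass(frozen=True)
class SpreadSummary:
    """Five-number-style summary of one (group, superkingdom) panel."""

    group: str
    superkingdom: str
    n_traits: int
    median_f: float
    quartiles: tuple[float, float]
    n_tail: int  # traits with f strictly above the tail threshold

    def __post_init__(self) -> None:
        q1, q3 = self.quartiles
        if not (0.0 <= q1 <= self.median_f <= q3 <= 1.0):
            raise ValidationError("summary quartiles out of order")
        if self.n_tail > self.n_traits:
            raise ValidationError("n_tail exceeds n_traits")


def f_value(
    trait_id: str,
    superkingdom: str,
    matrix: TraitMatrix,
    metadata: Sequence[OrganismRecord],
) -> float:
    """Fraction of the superkingdom's organisms carrying the trait."""
    blocks = organisms_by_superkingdom(matrix.organism_ids, metadata)
    orgs = blocks.get(superkingdom)
    if orgs is None:
        raise ConfigurationError(f"unknown superkingdom {superkingdom!r}")
    if not orgs:
        raise ConfigurationError(
            f"superkingdom {superkingdom} has no organisms; f undefined"
        )
    present = int(matrix.occurrence.loc[trait_id, orgs].sum())
    return present / len(orgs)


def spread_profiles(
    matrix: TraitMatrix,
    metadata: Sequence[OrganismRecord],
    assignments: Sequence[VennAssignment],
) -> list[SpreadProfile]:
    """One profile per trait, f defined exactly for its group's superkingdoms."""
    blocks = organisms_by_superkingdom(matrix.organism_ids, metadata)
    occ = matrix.occurrence
    f_all = {
        sk: occ[blocks[sk]].sum(axis=1) / len(blocks[sk])
        for sk in SUPERKINGDOMS
        if blocks[sk]
    }
    profiles = []
    for a in assignments:
        needed = [sk for sk in SUPERKINGDOMS if sk in a.group]
        missing = [sk for sk in needed if sk not in f_all]
        if missing:
            raise ConfigurationError(
                f"superkingdom(s) {missing} have no organisms; f undefined"
            )
        fs = {sk: float(f_all[sk][a.trait_id]) for sk in needed}
        profiles.append(
            SpreadProfile(trait_id=a.trait_id, venn_group=a.group, f_by_superkingdom=fs)
        )
    return profiles


def summarize_spread(
    profiles: Sequence[SpreadProfile],
    group: str,
    superkingdom: str,
    tail_threshold: float = 0.8,
) -> SpreadSummary | None:
    """Summarise one panel (Venn group x superkingdom) of the spread plot.

    Returns ``None`` when no trait of the group defines an f-value for the
    superkingdom (an empty panel, not an error).  Quartiles use linear
    interpolation.
    """
    values = np.array(
        [
            p.f_by_superkingdom[superkingdom]
            for p in profiles
            if p.venn_group == group and superkingdom in p.f_by_superkingdom
        ]
    )
    if values.size == 0:
        return None
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return SpreadSummary(
        group=group,
        superkingdom=superkingdom,
        n_traits=int(values.size),
        median_f=float(med),
        quartiles=(float(q1), float(q3)),
        n_tail=int((values > tail_threshold).sum()),
    )


def universal_core(matrix: TraitMatrix) -> list[str]:
    """Traits present in every retained organism (f = 1 everywhere)."""
    occ = matrix.occurrence
    mask = occ.all(axis=1)
    return list(occ.index[mask])


def near_universal(matrix: TraitMatrix, threshold: float = 0.90) -> list[str]:
    """Traits whose overall f (across all retained organisms) strictly
    exceeds ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ConfigurationError(f"threshold {threshold} outside [0, 1]")
    occ = matrix.occurrence
    overall = occ.sum(axis=1) / occ.shape[1]
    return list(overall.index[overall > threshold])
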