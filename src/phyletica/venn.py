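"""Venn taxonomic census.

Every trait with nonzero occurrence belongs to exactly one of seven mutually
exclusive sharing classes defined by which superkingdoms contain it: the
three superkingdom-specific groups A, B, E; the three two-superkingdom
groups AB, AE, BE; and the universal group ABE.  Presence in a superkingdom
is existential (at least one organism of that superkingdom carries the
trait); how widely the trait is spread is the business of the f-value
analysis, not the census.

Group labels always concatenate superkingdom letters in A < B < E order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .display import round_half_up
from .errors import ConfigurationError, ValidationError
from .io import SUPERKINGDOMS, OrganismRecord, TraitMatrix, records_by_id

__all__ = [
    "VENN_GROUPS",
    "TWO_SK_GROUPS",
    "VennAssignment",
    "VennCounts",
    "assign_venn_group",
    "assign_venn_groups",
    "venn_counts",
    "percentage_share",
    "organisms_by_superkingdom",
]

VENN_GROUPS = ("A", "B", "E", "AB", "AE", "BE", "ABE")
TWO_SK_GROUPS = ("AB", "AE", "BE")


@dataclass(frozen=True)
class VennAssignment:
    """A trait's presence flags per superkingdom and derived group label."""

    trait_id: str
    presence: tuple[bool, bool, bool]  # (A, B, E)
    group: str

    def __post_init__(self) -> None:
        expected = "".join(
            sk for sk, flag in zip(SUPERKINGDOMS, self.presence) if flag
        )
        if not expected:
            raise ValidationError(
                f"trait {self.trait_id}: absent from every superkingdom"
            )
        if self.group != expected:
            raise ValidationError(
                f"trait {self.trait_id}: group {self.group!r} inconsistent with "
                f"presence flags {self.presence} (expected {expected!r})"
            )


@dataclass(frozen=True)
class VennCounts:
    """Sizes of the seven groups; always sums to the number of traits."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValidationError("Venn group counts do not sum to total")

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "total": self.total}


def organisms_by_superkingdom(
    organism_ids: Sequence[str], metadata: Sequence[OrganismRecord]
) -> dict[str, list[str]]:
    """Partition organism ids into the three superkingdom blocks."""
    by_id = records_by_id(metadata)
    missing = [o for o in organism_ids if o not in by_id]
    if missing:
        raise ValidationError(f"organisms missing metadata: {missing[:10]}")
    blocks: dict[str, list[str]] = {sk: [] for sk in SUPERKINGDOMS}
    for org in organism_ids:
        blocks[by_id[org].superkingdom].append(org)
    return blocks


def _group_from_flags(flags: tuple[bool, bool, bool]) -> str:
    return "".join(sk for sk, flag in zip(SUPERKINGDOMS, flags) if flag)


def assign_venn_group(
    trait_id: str,
    occurrence: Mapping[str, bool],
    metadata: Sequence[OrganismRecord],
) -> VennAssignment:
    """Classify a single trait from its per-organism presence flags."""
    blocks = organisms_by_superkingdom(list(occurrence), metadata)
    empty = [sk for sk, orgs in blocks.items() if not orgs]
    if empty:
        raise ConfigurationError(
            f"superkingdom(s) {empty} have no organisms; Venn groups undefined"
        )
    flags = tuple(any(occurrence[o] for o in blocks[sk]) for sk in SUPERKINGDOMS)
    return VennAssignment(trait_id=trait_id, presence=flags, group=_group_from_flags(flags))


def assign_venn_groups(
    matrix: TraitMatrix, metadata: Sequence[OrganismRecord]
) -> list[VennAssignment]:
    """Classify every trait in the matrix (vectorised)."""
    blocks = organisms_by_superkingdom(matrix.organism_ids, metadata)
    empty = [sk for sk, orgs in blocks.items() if not orgs]
    if empty:
        raise ConfigurationError(
            f"superkingdom(s) {empty} have no organisms; Venn groups undefined"
        )
    occ = matrix.occurrence
    present = {sk: occ[blocks[sk]].any(axis=1) for sk in SUPERKINGDOMS}
    assignments = []
    for trait in matrix.trait_ids:
        flags = tuple(bool(present[sk][trait]) for sk in SUPERKINGDOMS)
        assignments.append(
            VennAssignment(trait_id=trait, presence=flags, group=_group_from_flags(flags))
        )
    return assignments


def venn_counts(assignments: Iterable[VennAssignment]) -> VennCounts:
    """Tabulate group sizes; raises on duplicate traits."""
    counts = {g: 0 for g in VENN_GROUPS}
    seen: set[str] = set()
    total = 0
    for a in assignments:
        if a.trait_id in seen:
            raise ValidationError(f"duplicate trait in assignments: {a.trait_id}")
        seen.add(a.trait_id)
        counts[a.group] += 1
        total += 1
    return VennCounts(counts=counts, total=total)


def percentage_share(count: int, total: int, *, rounded: bool = True) -> float | int:
    """Share of a group as a percentage of the total.

    With ``rounded=True`` (the display convention) the share is rounded to
    the nearest integer percent; otherwise the exact value is returned.
    """
    if total <= 0:
        raise ValidationError("percentage share undefined for total <= 0")
    if not (0 <= count <= total):
        raise ValidationError(f"count {count} outside [0, {total}]")
    share = 100.0 * count / total
    return round_half_up(share) if rounded else share
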