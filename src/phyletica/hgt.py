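"""Directional horizontal-transfer calls from f-value differences.

For a trait confined to two superkingdoms (groups AB, AE or BE), define
f_former and f_latter as its f-values in the first and second letter of the
group label, and f_difference = f_former - f_latter.  When
|f_difference| strictly exceeds a threshold (default 0.6) the trait's joint
presence is called a probable horizontal acquisition, directed from the
superkingdom with the larger spread (donor) to the smaller (recipient).
Traits below the threshold are counted as the group's vertical residual.

The rule is deliberately conservative: it flags only traits nearly
ubiquitous on one side yet scarce on the other.  Three-superkingdom (ABE)
and superkingdom-specific traits are never evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConsistencyError, NotApplicableError
from .spread import SpreadProfile
from .venn import TWO_SK_GROUPS, VennAssignment

__all__ = ["HGTCall", "FluxTally", "detect_hgt", "detect_all", "tally_flux"]


@dataclass(frozen=True)
class HGTCall:
    """A directional transfer candidate in a two-superkingdom group."""

    trait_id: str
    group: str
    f_former: float
    f_latter: float
    f_difference: float  # signed: f_former - f_latter
    donor: str
    recipient: str

    @property
    def direction(self) -> str:
        return f"{self.donor}->{self.recipient}"


@dataclass(frozen=True)
class FluxTally:
    """Direction-resolved call counts plus vertical residuals per group."""

    counts: dict[str, dict[str, int]]  # group -> direction -> n calls
    n_vertical: dict[str, int]
    group_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "counts": {g: dict(d) for g, d in self.counts.items()},
            "n_vertical": dict(self.n_vertical),
            "group_sizes": dict(self.group_sizes),
        }


def detect_hgt(profile: SpreadProfile, threshold: float = 0.6) -> HGTCall | None:
    """Apply the f-difference rule to one two-superkingdom trait.

    Returns a call iff |f_former - f_latter| > threshold (strict), ``None``
    otherwise.  Decisions use full-precision f; display rounding never
    affects the call.  Raises :class:`NotApplicableError` for traits outside
    AB/AE/BE.
    """
    group = profile.venn_group
    if group not in TWO_SK_GROUPS:
        raise NotApplicableError(
            f"trait {profile.trait_id}: HGT rule applies only to {TWO_SK_GROUPS}, "
            f"not {group}"
        )
    former, latter = group[0], group[1]
    f_former = profile.f_by_superkingdom[former]
    f_latter = profile.f_by_superkingdom[latter]
    diff = f_former - f_latter
    # strict inequality; guard against float representation noise so that
    # e.g. f-values 0.8 and 0.2 (difference exactly 0.6) stay below threshold
    if abs(diff) <= threshold or math.isclose(abs(diff), threshold, abs_tol=1e-12):
        return None
    donor, recipient = (former, latter) if diff > 0 else (latter, former)
    return HGTCall(
        trait_id=profile.trait_id,
        group=group,
        f_former=f_former,
        f_latter=f_latter,
        f_difference=diff,
        donor=donor,
        recipient=recipient,
    )


def detect_all(
    profiles: Iterable[SpreadProfile], threshold: float = 0.6
) -> list[HGTCall]:
    """Run the rule over the two-superkingdom traits, skipping the rest."""
    calls = []
    for p in profiles:
        if p.venn_group not in TWO_SK_GROUPS:
            continue
        call = detect_hgt(p, threshold=threshold)
        if call is not None:
            calls.append(call)
    return calls


def _directions(group: str) -> tuple[str, str]:
    a, b = group[0], group[1]
    return (f"{a}->{b}", f"{b}->{a}")


def tally_flux(
    calls: Sequence[HGTCall], assignments: Sequence[VennAssignment]
) -> FluxTally:
    """Count calls per (group, direction) and the vertical residual.

    For each two-superkingdom group: both direction counts plus the
    residual equal the group size.  A call whose trait is not assigned to
    its stated group raises :class:`ConsistencyError`.
    """
    group_of = {a.trait_id: a.group for a in assignments}
    sizes = {g: 0 for g in TWO_SK_GROUPS}
    for a in assignments:
        if a.group in sizes:
            sizes[a.group] += 1
    counts = {g: {d: 0 for d in _directions(g)} for g in TWO_SK_GROUPS}
    for call in calls:
        if group_of.get(call.trait_id) != call.group:
            raise ConsistencyError(
                f"call for {call.trait_id} states group {call.group} but the "
                f"assignment says {group_of.get(call.trait_id)}"
            )
        counts[call.group][call.direction] += 1
    n_vertical = {
        g: sizes[g] - sum(counts[g].values()) for g in TWO_SK_GROUPS
    }
    return FluxTally(counts=counts, n_vertical=n_vertical, group_sizes=sizes)
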