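"""Node-distance (nd) ages and evolutionary timelines.

The relative age of a trait is read off a rooted trait tree as its node
distance nd: count the internal nodes on the root-to-leaf path (root
included, leaf excluded) to get k, take K as the maximum over leaves, and
set nd = (k - 1) / (K - 1).  nd runs from 0 (a leaf attached directly to
the root: the most ancient) to 1 (the most derived leaves); for a star
tree (K = 1) every leaf gets nd = 0.  Branch lengths are ignored, so nd is
invariant to any rescaling of the tree.

Timelines join nd with each trait's Venn group and its per-superkingdom
abundance totals, ordered by ascending nd (ties broken by trait id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from .errors import StructuralError
from .io import SUPERKINGDOMS, OrganismRecord, TraitMatrix
from .venn import VennAssignment, organisms_by_superkingdom

__all__ = [
    "TimelineEntry",
    "load_trait_tree",
    "node_distance",
    "build_timeline",
    "most_ancient_per_group",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimelineEntry:
    trait_id: str
    nd: float
    venn_group: str
    abundance_by_superkingdom: Mapping[str, int]

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance_by_superkingdom.values())


def load_trait_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree whose leaf labels are trait ids."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise StructuralError(f"malformed trait tree {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise StructuralError(f"duplicate leaf labels in tree: {dupes[:5]}")
    return tree


def node_distance(tree: dendropy.Tree) -> dict[str, float]:
    """nd for every leaf of a rooted tree.

    k = number of internal nodes on the root-to-leaf path (root included);
    nd = (k - 1) / (K - 1) with K the maximum k; all zero for a star tree.
    """
    leaves = [n for n in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise StructuralError("nd requires a tree with at least 2 leaves")
    ks: dict[str, int] = {}
    for leaf in leaves:
        if leaf.taxon is None or leaf.taxon.label is None:
            raise StructuralError("every leaf must carry a trait id label")
        k = 0
        node = leaf.parent_node
        while node is not None:
            k += 1
            node = node.parent_node
        ks[leaf.taxon.label] = k
    big_k = max(ks.values())
    if big_k == 1:
        return {t: 0.0 for t in ks}
    return {t: (k - 1) / (big_k - 1) for t, k in ks.items()}


def build_timeline(
    nd_map: Mapping[str, float],
    assignments: Sequence[VennAssignment],
    matrix: TraitMatrix,
    metadata: Sequence[OrganismRecord],
) -> list[TimelineEntry]:
    """Join ages, Venn groups and per-superkingdom abundance totals.

    Traits in the assignments but absent from the tree are dropped with a
    logged count, not imputed.
    """
    blocks = organisms_by_superkingdom(matrix.organism_ids, metadata)
    sums = {
        sk: matrix.abundance[blocks[sk]].sum(axis=1) for sk in SUPERKINGDOMS
    }
    entries = []
    n_dropped = 0
    for a in assignments:
        if a.trait_id not in nd_map:
            n_dropped += 1
            continue
        entries.append(
            TimelineEntry(
                trait_id=a.trait_id,
                nd=float(nd_map[a.trait_id]),
                venn_group=a.group,
                abundance_by_superkingdom={
                    sk: int(sums[sk][a.trait_id]) for sk in SUPERKINGDOMS
                },
            )
        )
    if n_dropped:
        logger.info("timeline: dropped %d trait(s) absent from the tree", n_dropped)
    entries.sort(key=lambda e: (e.nd, e.trait_id))
    return entries


def most_ancient_per_group(entries: Sequence[TimelineEntry]) -> dict[str, str]:
    """Oldest trait per Venn group.

    Minimum nd wins; age ties are broken by maximum total abundance, then
    by trait id for determinism.  Groups without entries are absent from
    the mapping.
    """
    best: dict[str, TimelineEntry] = {}
    for e in entries:
        cur = best.get(e.venn_group)
        if cur is None:
            best[e.venn_group] = e
            continue
        key_new = (e.nd, -e.total_abundance, e.trait_id)
        key_cur = (cur.nd, -cur.total_abundance, cur.trait_id)
        if key_new < key_cur:
            best[e.venn_group] = e
    return {g: e.trait_id for g, e in best.items()}
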