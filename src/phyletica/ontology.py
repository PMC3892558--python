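"""Level-1 mapping of terminal ontology terms.

A molecular-function ontology is read as a directed acyclic graph of is_a
links (child -> parent).  Level-1 terms are the direct is_a children of the
root.  Each terminal term submitted by the caller is climbed to the set of
level-1 ancestors it reaches; terms reaching more than one level-1 parent
are counted once per parent.  A terminal that is itself level-1 (or the
root, or disconnected from the root) has no level-1 *parent* and is
reported as unmapped with a reason code.

Only is_a edges are traversed; part_of, regulates and other relationship
types are ignored.  "Terminal" status is taken from the caller's trait
list, not recomputed from the DAG's leaves, because which annotations are
terminal is a property of the annotation pipeline, not of the ontology
graph alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import obonet

from .display import display_percent
from .errors import ConfigurationError, StructuralError, ValidationError

__all__ = [
    "OntologyDAG",
    "Level1Breakdown",
    "load_ontology",
    "map_to_level1",
    "level1_breakdown",
    "mapped_percentage",
    "write_obo",
]

UNMAPPED_REASONS = ("level1_terminal", "root_terminal", "disconnected", "missing")


@dataclass(frozen=True)
class OntologyDAG:
    """is_a hierarchy: a DAG with edges child -> parent and a single root."""

    graph: nx.DiGraph
    root: str
    level1: frozenset[str]
    names: Mapping[str, str] = field(default_factory=dict)
    n_obsolete_skipped: int = 0

    def name_of(self, term: str) -> str:
        return self.names.get(term, term)


def _find_root(graph: nx.DiGraph) -> str:
    # the root is the unique term with is_a parents pointing at it but no
    # is_a parent of its own; isolated terms are disconnected, not roots
    candidates = [
        n for n in graph.nodes if graph.out_degree(n) == 0 and graph.in_degree(n) > 0
    ]
    if len(candidates) != 1:
        raise ConfigurationError(
            f"expected exactly one root term, found {len(candidates)}: "
            f"{sorted(candidates)[:5]}"
        )
    return candidates[0]


def build_dag(
    edges: Sequence[tuple[str, str]],
    terms: Sequence[str] | None = None,
    names: Mapping[str, str] | None = None,
    root: str | None = None,
    n_obsolete_skipped: int = 0,
) -> OntologyDAG:
    """Assemble and validate an :class:`OntologyDAG` from is_a edges."""
    graph = nx.DiGraph()
    if terms:
        graph.add_nodes_from(terms)
    graph.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise StructuralError(f"is_a cycle detected: {cycle}")
    if root is None:
        root = _find_root(graph)
    elif root not in graph:
        raise ConfigurationError(f"designated root {root!r} absent from ontology")
    level1 = frozenset(graph.predecessors(root))
    return OntologyDAG(
        graph=graph,
        root=root,
        level1=level1,
        names=dict(names or {}),
        n_obsolete_skipped=n_obsolete_skipped,
    )


def load_ontology(path: str | Path, root: str | None = None) -> OntologyDAG:
    """Read an OBO file, keeping term stanzas and is_a edges only.

    Obsolete terms are skipped (their count is recorded on the returned
    DAG).  Cycles raise :class:`StructuralError`; an ambiguous or missing
    root raises :class:`ConfigurationError` unless ``root`` is given.
    """
    multigraph = obonet.read_obo(path)
    # obonet silently drops obsolete stanzas; recover the count by scanning
    text = Path(path).read_text()
    n_obsolete = text.count("is_obsolete: true")
    edges = [
        (child, parent)
        for child, parent, key in multigraph.edges(keys=True)
        if key == "is_a"
    ]
    names = {
        n: data.get("name", n) for n, data in multigraph.nodes(data=True)
    }
    return build_dag(
        edges,
        terms=list(multigraph.nodes),
        names=names,
        root=root,
        n_obsolete_skipped=n_obsolete,
    )


def map_to_level1(term: str, dag: OntologyDAG) -> frozenset[str]:
    """Set of level-1 ancestors reachable from ``term`` by is_a traversal.

    A level-1 term maps to itself; an empty set means the term has no
    level-1 ancestry (disconnected, or the root itself).
    """
    if term not in dag.graph:
        raise LookupError(f"unknown ontology term {term!r}")
    ancestors = nx.descendants(dag.graph, term)  # edges run child -> parent
    reachable = set(ancestors)
    reachable.add(term)
    return frozenset(reachable & dag.level1)


@dataclass
class Level1Breakdown:
    """Counts of terminal terms per (level-1 parent, Venn group)."""

    counts: dict[tuple[str, str], int]
    n_mapped: int
    n_unmapped: int
    unmapped_ids: list[tuple[str, str]]  # (term, reason code)
    groups_per_level1: dict[str, frozenset[str]]

    @property
    def n_submitted(self) -> int:
        return self.n_mapped + self.n_unmapped

    def table_total(self) -> int:
        return sum(self.counts.values())


def level1_breakdown(
    terminals: Mapping[str, str], dag: OntologyDAG
) -> Level1Breakdown:
    """Map each terminal term (with its Venn group) to level-1 parents.

    ``terminals`` maps term id -> Venn group label.  Multi-parent terms are
    counted once per parent, so the table total can exceed ``n_mapped``.
    A term counts as mapped only when it reaches a level-1 term *above*
    itself; level-1 and root terminals, terms disconnected from the root,
    and terms absent from the DAG land in ``unmapped_ids`` with reason
    codes.  Counts are independent of submission order.
    """
    counts: dict[tuple[str, str], int] = {}
    unmapped: list[tuple[str, str]] = []
    groups: dict[str, set[str]] = {}
    n_mapped = 0
    for term in sorted(terminals):
        group = terminals[term]
        if term not in dag.graph:
            unmapped.append((term, "missing"))
            continue
        if term == dag.root:
            unmapped.append((term, "root_terminal"))
            continue
        if term in dag.level1:
            unmapped.append((term, "level1_terminal"))
            continue
        parents = nx.descendants(dag.graph, term) & dag.level1
        if not parents:
            unmapped.append((term, "disconnected"))
            continue
        n_mapped += 1
        for parent in parents:
            counts[(parent, group)] = counts.get((parent, group), 0) + 1
            groups.setdefault(parent, set()).add(group)
    return Level1Breakdown(
        counts=counts,
        n_mapped=n_mapped,
        n_unmapped=len(unmapped),
        unmapped_ids=unmapped,
        groups_per_level1={k: frozenset(v) for k, v in groups.items()},
    )


def mapped_percentage(breakdown: Level1Breakdown) -> float:
    """Percentage of submitted terminals with a level-1 parent (2 dp,
    truncated)."""
    total = breakdown.n_submitted
    if total <= 0:
        raise ValidationError("mapped percentage undefined: no terms submitted")
    return display_percent(100.0 * breakdown.n_mapped / total, 2)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialise the DAG as a minimal OBO document ([Term] stanzas with
    id/name/is_a), parseable by :func:`load_ontology`."""
    lines = ["format-version: 1.2", "ontology: synthetic-molecular-function", ""]
    for term in sorted(dag.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.name_of(term)}")
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent} ! {dag.name_of(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
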