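"""Ontology level-1 mapping: traversal, multi-parent counting, unmapped
accounting, OBO round-trips."""

import numpy as np
import pytest

from phyletica import (
    build_dag,
    level1_breakdown,
    load_ontology,
    map_to_level1,
    mapped_percentage,
    simulate_ontology,
    write_obo,
)
from phyletica.errors import ConfigurationError, StructuralError
from phyletica.ontology import Level1Breakdown

TOY_OBO = """format-version: 1.2

[Term]
id: X:0
name: root

[Term]
id: X:1
name: catalytic activity
is_a: X:0 ! root

[Term]
id: X:2
name: binding
is_a: X:0 ! root

[Term]
id: X:3
name: kinase activity
is_a: X:1 ! catalytic activity

[Term]
id: X:4
name: ATP binding kinase
is_a: X:1 ! catalytic activity
is_a: X:2 ! binding

[Term]
id: X:9
name: orphan activity
"""


@pytest.fixture
def toy_dag(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return load_ontology(path)


class TestLoadOntology:
    def test_level1_detection(self, toy_dag):
        assert toy_dag.root == "X:0"
        assert toy_dag.level1 == {"X:1", "X:2"}
        assert toy_dag.name_of("X:1") == "catalytic activity"

    def test_multi_parent_out_degree(self, toy_dag):
        assert toy_dag.graph.out_degree("X:4") == 2

    def test_cycle_detected(self, tmp_path):
        path = tmp_path / "cyc.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: a\nname: a\nis_a: b ! b\n\n"
            "[Term]\nid: b\nname: b\nis_a: a ! a\n"
        )
        with pytest.raises(StructuralError):
            load_ontology(path)

    def test_ambiguous_root_needs_designation(self):
        with pytest.raises(ConfigurationError):
            build_dag([("c1", "r1"), ("c2", "r2")])
        dag = build_dag([("c1", "r1"), ("c2", "r2")], root="r1")
        assert dag.root == "r1"

    def test_obsolete_terms_skipped_with_count(self, tmp_path):
        path = tmp_path / "obs.obo"
        path.write_text(
            TOY_OBO + "\n[Term]\nid: X:8\nname: gone\nis_obsolete: true\n"
            "is_a: X:1 ! catalytic activity\n"
        )
        dag = load_ontology(path)
        assert "X:8" not in dag.graph
        assert dag.n_obsolete_skipped == 1


class TestMapToLevel1:
    def test_single_subtree_leaf(self, toy_dag):
        assert map_to_level1("X:3", toy_dag) == {"X:1"}

    def test_multi_parent_leaf(self, toy_dag):
        assert map_to_level1("X:4", toy_dag) == {"X:1", "X:2"}

    def test_level1_maps_to_itself(self, toy_dag):
        assert map_to_level1("X:1", toy_dag) == {"X:1"}

    def test_disconnected_maps_to_empty(self, toy_dag):
        assert map_to_level1("X:9", toy_dag) == frozenset()

    def test_unknown_term_lookup_error(self, toy_dag):
        with pytest.raises(LookupError):
            map_to_level1("X:404", toy_dag)


class TestBreakdown:
    def test_accounting_identities(self, toy_dag):
        terminals = {"X:3": "ABE", "X:4": "BE", "X:1": "E", "X:9": "A"}
        b = level1_breakdown(terminals, toy_dag)
        assert b.n_mapped == 2
        assert b.n_unmapped == 2
        assert b.n_mapped + b.n_unmapped == len(terminals)
        assert b.table_total() == 3  # X:4 counted once per parent
        assert b.table_total() >= b.n_mapped
        reasons = dict(b.unmapped_ids)
        assert reasons == {"X:1": "level1_terminal", "X:9": "disconnected"}

    def test_order_invariance(self, toy_dag):
        terminals = {"X:3": "ABE", "X:4": "BE"}
        b1 = level1_breakdown(terminals, toy_dag)
        b2 = level1_breakdown(dict(reversed(list(terminals.items()))), toy_dag)
        assert b1.counts == b2.counts

    def test_unique_group_attribution(self, toy_dag):
        # construct: one level-1 parent fed only by BE/E terminals, the other
        # shared; no group among A, B, AB, AE uniquely holds a parent
        terminals = {"X:3": "E", "X:4": "BE"}
        b = level1_breakdown(terminals, toy_dag)
        assert b.groups_per_level1["X:2"] == {"BE"}
        assert b.groups_per_level1["X:1"] == {"E", "BE"}
        for groups in b.groups_per_level1.values():
            assert not groups <= {"A", "B", "AB", "AE"}

    def test_traversal_matches_transitive_closure_oracle(self):
        """Random layered DAGs up to 200 nodes: the library climb equals an
        explicit DFS over a plain adjacency dict."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            edges = [(f"n{i}", f"n{int(rng.integers(max(1, i // 2), i))}")
                     for i in range(2, n)]
            edges = [(c, p if p != c else "n1") for c, p in edges]
            edges.append(("n1", "n0"))
            dag = build_dag(edges, root="n0")
            adjacency = {}
            for child, parent in edges:
                adjacency.setdefault(child, set()).add(parent)

            def closure(term):
                seen, stack = set(), [term]
                while stack:
                    node = stack.pop()
                    for p in adjacency.get(node, ()):
                        if p not in seen:
                            seen.add(p)
                            stack.append(p)
                return seen

            for i in range(n):
                term = f"n{i}"
                if term not in dag.graph:
                    continue
                expected = (closure(term) | {term}) & dag.level1
                assert map_to_level1(term, dag) == expected

    def test_removing_intermediate_preserves_level1_sets(self, toy_dag):
        """Splicing out a non-root, non-level-1 node and reconnecting its
        children to its parents leaves every terminal's mapping unchanged."""
        edges = [
            ("L1a", "root"), ("L1b", "root"),
            ("mid", "L1a"), ("leaf1", "mid"), ("leaf2", "mid"), ("leaf3", "L1b"),
        ]
        dag = build_dag(edges, root="root")
        spliced = build_dag(
            [("L1a", "root"), ("L1b", "root"), ("leaf1", "L1a"),
             ("leaf2", "L1a"), ("leaf3", "L1b")],
            root="root",
        )
        for leaf in ("leaf1", "leaf2", "leaf3"):
            assert map_to_level1(leaf, dag) == map_to_level1(leaf, spliced)


class TestMappedPercentage:
    def test_display_truncation(self):
        b = Level1Breakdown({}, n_mapped=1871, n_unmapped=53, unmapped_ids=[],
                            groups_per_level1={})
        assert mapped_percentage(b) == 97.24

    @pytest.mark.parametrize("mapped,unmapped,expected", [(5, 0, 100.0), (0, 5, 0.0)])
    def test_extremes(self, mapped, unmapped, expected):
        b = Level1Breakdown({}, mapped, unmapped, [], {})
        assert mapped_percentage(b) == expected


class TestSimulatedOntology:
    def test_single_parent_when_multi_parent_disabled(self):
        dag, terminals = simulate_ontology(
            n_level1=5, n_terminal=40, multi_parent_prob=0.0, seed=1
        )
        for t in terminals:
            assert len(map_to_level1(t, dag)) == 1

    def test_sixteen_level1_parents(self):
        dag, terminals = simulate_ontology(n_level1=16, n_terminal=64, seed=2)
        assert len(dag.level1) == 16
        groups = {t: "ABE" for t in terminals}
        b = level1_breakdown(groups, dag)
        assert b.n_mapped == 64
        assert len({l1 for l1, _ in b.counts}) <= 16

    def test_obo_round_trip(self, tmp_path):
        dag, terminals = simulate_ontology(
            n_level1=4, n_terminal=25, multi_parent_prob=0.3, seed=3
        )
        path = tmp_path / "sim.obo"
        write_obo(dag, path)
        reloaded = load_ontology(path)
        assert set(reloaded.graph.nodes) == set(dag.graph.nodes)
        assert set(reloaded.graph.edges) == set(dag.graph.edges)
        assert reloaded.level1 == dag.level1
        for t in terminals[:10]:
            assert map_to_level1(t, reloaded) == map_to_level1(t, dag)
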