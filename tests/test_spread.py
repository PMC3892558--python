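"""f-value computation, panel summaries and universal cores."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_matrix, small_params
from phyletica import (
    OrganismRecord,
    TraitMatrix,
    assign_venn_groups,
    f_value,
    near_universal,
    spread_profiles,
    summarize_spread,
    universal_core,
)
from phyletica.display import display_f
from phyletica.errors import ConfigurationError
from phyletica.simulate import simulate_repertoires
from phyletica.spread import SpreadProfile


def _one_of_652_matrix():
    """A trait present in exactly 1 of 652 bacteria (plus two other blocks)."""
    orgs = (
        [f"B{i:03d}" for i in range(652)]
        + ["A000", "E000"]
    )
    records = [OrganismRecord(o, o[0], "free_living", 1.0) for o in orgs]
    row = [0] * 654
    row[0] = 1       # the single bacterial occurrence
    row[-1] = 3      # a eukaryal foothold so the trait is BE
    df = pd.DataFrame([row], index=["rare"], columns=orgs)
    return TraitMatrix(df), records


class TestFValue:
    def test_singleton_among_652_reports_0_001(self):
        matrix, records = _one_of_652_matrix()
        f = f_value("rare", "B", matrix, records)
        assert f == pytest.approx(1 / 652)
        assert display_f(f) == 0.001

    def test_ubiquitous_is_one_and_absent_is_zero(self, toy_matrix, toy_records):
        assert f_value("t1", "A", toy_matrix, toy_records) == 1.0
        assert f_value("t3", "B", toy_matrix, toy_records) == 0.0

    def test_empty_superkingdom_undefined(self, toy_matrix, toy_records):
        no_a = [r for r in toy_records if r.superkingdom != "A"]
        sub = toy_matrix.subset(organisms=[r.organism_id for r in no_a])
        with pytest.raises(ConfigurationError):
            f_value("t1", "A", sub, no_a)


class TestProfiles:
    def test_defined_only_for_group_superkingdoms(self, toy_matrix, toy_records):
        assignments = assign_venn_groups(toy_matrix, toy_records)
        profiles = {p.trait_id: p for p in spread_profiles(toy_matrix, toy_records, assignments)}
        be = profiles["t2"]
        assert set(be.f_by_superkingdom) == {"B", "E"}
        assert be.f_by_superkingdom["B"] == 0.5
        assert be.f_by_superkingdom["E"] == 1.0
        abe = profiles["t1"]
        assert abe.f_by_superkingdom == {"A": 1.0, "B": 1.0, "E": 1.0}

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            matrix, records = random_matrix(rng, 20, 12)
            assignments = assign_venn_groups(matrix, records)
            profiles = spread_profiles(matrix, records, assignments)
            sk_of = {r.organism_id: r.superkingdom for r in records}
            for p in profiles:
                for sk, f in p.f_by_superkingdom.items():
                    orgs = [o for o in matrix.organism_ids if sk_of[o] == sk]
                    n_present = sum(
                        matrix.abundance.loc[p.trait_id, o] >= 1 for o in orgs
                    )
                    assert f == pytest.approx(n_present / len(orgs))

    def test_f_zero_iff_letter_absent_from_group(self, small_sim):
        params, matrix, metadata, truth = small_sim
        assignments = assign_venn_groups(matrix, metadata)
        from phyletica.venn import organisms_by_superkingdom

        blocks = organisms_by_superkingdom(matrix.organism_ids, metadata)
        occ = matrix.occurrence
        for a in assignments[:200]:
            for sk in "ABE":
                f = occ.loc[a.trait_id, blocks[sk]].mean()
                assert (f == 0) == (sk not in a.group)


class TestSummaries:
    def _profiles(self, fs, group="BE", sk="B"):
        return [
            SpreadProfile(f"p{i}", group, {sk: f, group.replace(sk, ""): 1.0})
            for i, f in enumerate(fs)
        ]

    def test_median_and_tail(self):
        s = summarize_spread(self._profiles([0.1, 0.2, 0.3]), "BE", "B")
        assert s.median_f == pytest.approx(0.2)
        assert s.n_tail == 0

    def test_tail_counts_strictly_above(self):
        s = summarize_spread(
            self._profiles([0.85, 0.9, 0.95, 0.5, 0.8]), "BE", "B", tail_threshold=0.8
        )
        assert s.n_tail == 3  # 0.8 itself is not in the tail

    def test_empty_panel_sentinel(self):
        assert summarize_spread([], "AE", "A") is None


class TestUniversalCores:
    def test_strict_universality(self, toy_records):
        orgs = [r.organism_id for r in toy_records]
        df = pd.DataFrame(
            [[1] * 6, [1] * 5 + [0]], index=["all", "all_but_one"], columns=orgs
        )
        m = TraitMatrix(df)
        assert universal_core(m) == ["all"]

    def test_near_universal_boundary(self):
        orgs = [f"B{i:03d}" for i in range(100)]
        records = [OrganismRecord(o, "B", "free_living", 1.0) for o in orgs]
        df = pd.DataFrame(
            [[1] * 91 + [0] * 9, [1] * 90 + [0] * 10],
            index=["in91", "in90"],
            columns=orgs,
        )
        m = TraitMatrix(df)
        assert near_universal(m, 0.90) == ["in91"]  # strict >
        assert set(near_universal(m, 0.0)) == {"in91", "in90"}

    def test_core_subset_of_near_universal_and_antitone(self, small_sim):
        params, matrix, metadata, truth = small_sim
        core = set(universal_core(matrix))
        for theta in (0.0, 0.5, 0.9):
            assert core <= set(near_universal(matrix, theta))
        assert set(near_universal(matrix, 0.9)) <= set(near_universal(matrix, 0.5))

    def test_no_loss_core_equals_urancestral_set(self):
        params = small_params(
            archaeal_loss_rate=0.0,
            archaeal_lineage_loss_rate=0.0,
            late_bacterial_loss_rate=0.0,
            n_hgt=0,
        )
        matrix, metadata, truth = simulate_repertoires(params)
        expected = {
            t.trait_id
            for t in truth.traits.values()
            if t.trait_class == "urancestral"
        }
        assert set(universal_core(matrix)) == expected


class TestArchaealLossSignature:
    def test_patchy_archaeal_loss_lowers_only_archaeal_medians(self):
        """Raising within-superkingdom archaeal loss strictly lowers the
        median archaeal f of ABE traits; bacterial and eukaryal medians are
        untouched in expectation."""
        medians = {rate: {"A": [], "B": [], "E": []} for rate in (0.0, 0.25, 0.5)}
        for rate in medians:
            for seed in range(20):
                params = small_params(
                    archaeal_loss_rate=0.0,
                    archaeal_lineage_loss_rate=rate,
                    late_bacterial_loss_rate=0.0,
                    n_hgt=0,
                    seed=seed,
                )
                matrix, metadata, truth = simulate_repertoires(params)
                assignments = assign_venn_groups(matrix, metadata)
                profiles = spread_profiles(matrix, metadata, assignments)
                for sk in "ABE":
                    s = summarize_spread(profiles, "ABE", sk)
                    medians[rate][sk].append(s.median_f)
        mean_a = {rate: np.mean(vals["A"]) for rate, vals in medians.items()}
        assert mean_a[0.0] > mean_a[0.25] > mean_a[0.5]
        for rate in (0.25, 0.5):
            assert np.mean(medians[rate]["B"]) == pytest.approx(
                np.mean(medians[0.0]["B"]), abs=1e-9
            )
            assert np.mean(medians[rate]["E"]) == pytest.approx(
                np.mean(medians[0.0]["E"]), abs=1e-9
            )
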