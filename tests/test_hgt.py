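"""The f-difference transfer rule: boundary, symmetry, monotonicity and
planted-transfer recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import small_params
from phyletica import (
    assign_venn_groups,
    detect_all,
    detect_hgt,
    spread_profiles,
    tally_flux,
)
from phyletica.errors import ConsistencyError, NotApplicableError
from phyletica.hgt import HGTCall
from phyletica.simulate import simulate_repertoires
from phyletica.spread import SpreadProfile
from phyletica.venn import VennAssignment


def be_profile(trait, f_b, f_e):
    return SpreadProfile(trait, "BE", {"B": f_b, "E": f_e})


class TestDetect:
    def test_eukarya_to_bacteria_example(self):
        # t-snare pattern: near-ubiquitous in Eukarya, one bacterial find
        call = detect_hgt(be_profile("snare", 1 / 652, 0.996))
        assert call is not None
        assert call.donor == "E" and call.recipient == "B"
        assert call.f_difference == pytest.approx(1 / 652 - 0.996)

    def test_boundary_is_strict(self):
        assert detect_hgt(be_profile("edge", 0.8, 0.2)) is None  # diff exactly 0.6
        assert detect_hgt(be_profile("over", 0.81, 0.2)) is not None

    def test_equal_f_no_call(self):
        assert detect_hgt(be_profile("tie", 0.5, 0.5)) is None

    def test_three_superkingdom_group_not_applicable(self):
        p = SpreadProfile("x", "ABE", {"A": 1.0, "B": 1.0, "E": 0.1})
        with pytest.raises(NotApplicableError):
            detect_hgt(p)

    def test_single_superkingdom_group_not_applicable(self):
        with pytest.raises(NotApplicableError):
            detect_hgt(SpreadProfile("x", "B", {"B": 0.9}))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        f1=st.floats(0.001, 1.0),
        f2=st.floats(0.001, 1.0),
        theta=st.floats(0.0, 1.0),
    )
    def test_antisymmetry(self, f1, f2, theta):
        """Swapping the two f-values flips donor/recipient and negates the
        difference; the call decision itself is unchanged."""
        a = detect_hgt(be_profile("t", f1, f2), threshold=theta)
        b = detect_hgt(be_profile("t", f2, f1), threshold=theta)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.f_difference == pytest.approx(-b.f_difference)
            assert (a.donor, a.recipient) == (b.recipient, b.donor)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        profiles = [
            be_profile(f"t{i}", rng.random(), rng.random()) for i in range(300)
        ]
        called = {
            theta: {c.trait_id for c in detect_all(profiles, threshold=theta)}
            for theta in (0.2, 0.4, 0.6, 0.8)
        }
        assert called[0.8] <= called[0.6] <= called[0.4] <= called[0.2]


class TestTally:
    def _assignments(self, sizes):
        out = []
        presence = {"AB": (True, True, False), "AE": (True, False, True),
                    "BE": (False, True, True)}
        for group, n in sizes.items():
            out.extend(
                VennAssignment(f"{group}_{i}", presence[group], group)
                for i in range(n)
            )
        return out

    def test_vertical_residual_accounting(self):
        """A 324-trait BE group with 35 B->E and 52 E->B calls leaves 237
        vertical traits."""
        assignments = self._assignments({"BE": 324})
        profiles = []
        for i, a in enumerate(assignments):
            if i < 35:
                profiles.append(be_profile(a.trait_id, 0.95, 0.05))  # B -> E
            elif i < 87:
                profiles.append(be_profile(a.trait_id, 0.05, 0.95))  # E -> B
            else:
                profiles.append(be_profile(a.trait_id, 0.5, 0.6))
        calls = detect_all(profiles)
        tally = tally_flux(calls, assignments)
        assert tally.counts["BE"] == {"B->E": 35, "E->B": 52}
        assert tally.n_vertical["BE"] == 237
        assert (
            sum(tally.counts["BE"].values()) + tally.n_vertical["BE"]
            == tally.group_sizes["BE"]
        )

    def test_no_calls_all_vertical(self):
        assignments = self._assignments({"AB": 5, "BE": 7})
        tally = tally_flux([], assignments)
        assert tally.n_vertical == {"AB": 5, "AE": 0, "BE": 7}

    def test_inconsistent_call_rejected(self):
        assignments = self._assignments({"BE": 2})
        rogue = HGTCall("not_there", "BE", 0.9, 0.1, 0.8, "B", "E")
        with pytest.raises(ConsistencyError):
            tally_flux([rogue], assignments)


class TestPlantedRecovery:
    def test_designed_gap_precision_and_recall(self):
        """Donor spread >= 0.9 and recipient spread <= 0.2 guarantee an
        f-gap beyond 0.6; every planted transfer is called and nothing
        else is (both-sides-ubiquitous traits stay silent)."""
        params = small_params(
            archaeal_loss_rate=0.3,
            archaeal_lineage_loss_rate=0.0,
            late_bacterial_loss_rate=0.0,
            n_hgt=10,
            seed=3,
        )
        matrix, metadata, truth = simulate_repertoires(params)
        assignments = assign_venn_groups(matrix, metadata)
        profiles = spread_profiles(matrix, metadata, assignments)
        called = {c.trait_id for c in detect_all(profiles, threshold=0.6)}
        planted = {
            t.trait_id for t in truth.traits.values() if t.trait_class == "hgt"
        }
        assert called == planted  # precision = recall = 1
        # stem-loss BE traits are ubiquitous on both sides: never called
        stem = {t.trait_id for t in truth.traits.values() if t.trait_class == "be_stem"}
        assert not (called & stem)

    def test_call_direction_matches_planted_direction(self):
        params = small_params(n_hgt=12, archaeal_lineage_loss_rate=0.0,
                              late_bacterial_loss_rate=0.0, seed=9)
        matrix, metadata, truth = simulate_repertoires(params)
        assignments = assign_venn_groups(matrix, metadata)
        calls = detect_all(spread_profiles(matrix, metadata, assignments))
        by_id = {c.trait_id: c for c in calls}
        for t in truth.traits.values():
            if t.trait_class != "hgt":
                continue
            call = by_id[t.trait_id]
            assert (call.donor, call.recipient) == (t.hgt_donor, t.hgt_recipient)

    def test_recall_degrades_as_recipient_spread_rises(self):
        """With common random draws, widening the recipient-spread range
        toward the donor range can only shrink the called set."""
        rng = np.random.default_rng(17)
        n = 60
        donor_f = 0.9 + 0.1 * rng.random(n)
        u = rng.random(n)  # shared uniforms scaled by the upper bound
        recalls = []
        for upper in (0.1, 0.3, 0.5, 0.7, 0.9):
            recipient_f = np.maximum(u * upper, 1e-3)
            profiles = [
                be_profile(f"t{i}", donor_f[i], recipient_f[i]) for i in range(n)
            ]
            recalls.append(len(detect_all(profiles, threshold=0.6)) / n)
        assert recalls[0] == 1.0
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        assert recalls[-1] < 1.0
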