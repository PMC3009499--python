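"""Grouping, consensus construction, confidence and dual-topology reporting."""

import numpy as np
import pytest

from kbestpaths import (
    Hmm,
    ScoredPath,
    Sequence,
    confidence_report,
    consensus_boundary_average,
    consensus_helix_vote,
    consensus_position_vote,
    forward_log_prob,
    group_paths,
    heaviest_group,
    kbest_naive,
    sample_sequence,
    top_groups,
    topology_of,
)
from kbestpaths.analysis import GroupMember, TopologyGroup, labelling_feasible, probability_band


def make_group(labelled_weights):
    members = [
        GroupMember(
            path=ScoredPath(states=("x",) * len(lab), log_joint=0.0, rank=i + 1),
            labelling=lab,
            topology=topology_of(lab),
            cond_prob=w,
        )
        for i, (lab, w) in enumerate(labelled_weights)
    ]
    t = members[0].topology
    return TopologyGroup(
        topology_key=(t.helix_count, t.sidedness),
        members=members,
        weight=sum(w for _, w in labelled_weights),
    )


class TestGrouping:
    def test_unanimous_paths_form_one_group(self, toy):
        seq, _ = sample_sequence(toy, 60, seed=2)
        res = kbest_naive(toy, seq, 3)
        groups = group_paths(toy, seq, res)
        total = sum(g.weight for g in groups)
        assert sum(g.size for g in groups) == len(res.paths)
        # group weights re-sum to the total conditional mass of the result
        log_z = forward_log_prob(toy, seq)
        direct = sum(np.exp(p.log_joint - log_z) for p in res.paths)
        assert total == pytest.approx(direct, abs=1e-9)

    def test_mirror_model_produces_sided_pair(self, mirror):
        seq, _ = sample_sequence(mirror, 40, seed=5)
        res = kbest_naive(mirror, seq, 16)
        groups = group_paths(mirror, seq, res)
        assert len(groups) >= 2
        sides = {groups[0].topology_key[1], groups[1].topology_key[1]}
        assert sides == {"i", "o"}

    def test_heaviest_group_is_first_and_errors_on_empty(self, toy):
        seq, _ = sample_sequence(toy, 50, seed=3)
        groups = group_paths(toy, seq, kbest_naive(toy, seq, 8))
        assert heaviest_group(groups) is groups[0]
        assert groups[0].weight == max(g.weight for g in groups)
        with pytest.raises(ValueError):
            heaviest_group([])


class TestBoundaryAverage:
    def test_single_member_returns_its_own_labelling(self):
        grp = make_group([("iiMMMMMoo", 0.5)])
        assert consensus_boundary_average(grp).labels == "iiMMMMMoo"

    def test_two_members_average_arithmetically(self):
        # helices [10,20) and [12,22) average to [11,21)
        a = "i" * 10 + "M" * 10 + "o" * 10
        b = "i" * 12 + "M" * 10 + "o" * 8
        cons = consensus_boundary_average(make_group([(a, 0.3), (b, 0.3)]))
        assert cons.labels == "i" * 11 + "M" * 10 + "o" * 9
        assert cons.consistent is True

    def test_collision_after_rounding_is_repaired(self):
        # averaged helices would touch; repair must keep two helices
        a = "i" + "M" * 5 + "o" + "M" * 5 + "i" * 8
        b = "i" * 3 + "M" * 5 + "o" + "M" * 5 + "i" * 6
        cons = consensus_boundary_average(make_group([(a, 0.4), (b, 0.4)]))
        topo = topology_of(cons.labels)
        assert topo.helix_count == 2
        assert topo.sidedness == "i"

    @pytest.mark.parametrize("seed", range(12))
    def test_consensus_topology_equals_group_key(self, toy, seed):
        seq, _ = sample_sequence(toy, 150, seed=9000 + seed)
        res = kbest_naive(toy, seq, 30)
        for grp in group_paths(toy, seq, res):
            cons = consensus_boundary_average(grp)
            topo = topology_of(cons.labels)
            assert (topo.helix_count, topo.sidedness) == grp.topology_key


class TestVoting:
    def test_unanimous_vote_returns_the_common_labelling(self, toy):
        seq, _ = sample_sequence(toy, 30, seed=11)
        res = kbest_naive(toy, seq, 1)
        cons = consensus_position_vote(toy, seq, res)
        assert cons.labels == group_paths(toy, seq, res)[0].members[0].labelling

    def test_dominant_path_wins_every_position(self):
        h = _two_label_hmm()
        seq = Sequence("t", "aab")
        res = kbest_naive(h, seq, 4)
        log_z = forward_log_prob(h, seq)
        weights = [np.exp(p.log_joint - log_z) for p in res.paths]
        if weights[0] > 0.5:
            cons = consensus_position_vote(h, seq, res)
            top_lab = "".join(h.label_of(s) for s in res.paths[0].states)
            assert cons.labels == top_lab

    def test_vote_can_match_no_member(self, toy):
        # members ioo/oio/iii with weights .35/.35/.30: the per-position
        # winner is iio, a labelling held by no member
        members = [("ioo", 0.35), ("oio", 0.35), ("iii", 0.30)]
        grp = make_group(members)
        seq = Sequence("t", "hhh")
        cons = consensus_position_vote(toy, seq, grp)
        assert cons.labels == "iio"
        assert cons.labels not in {m.labelling for m in grp.members}

    def test_helix_vote_single_member(self):
        grp = make_group([("iiMMMMMoo", 1.0)])
        h = _two_label_hmm()
        cons = consensus_helix_vote(h, Sequence("t", "a" * 9), grp)
        assert cons.labels == "iiMMMMMoo"

    def test_helix_vote_modal_pair_beats_outlier(self):
        common = "ii" + "M" * 6 + "oo"
        outlier = "iiii" + "M" * 5 + "o"
        grp = make_group([(common, 0.3), (common, 0.3), (outlier, 0.2)])
        h = _two_label_hmm()
        cons = consensus_helix_vote(h, Sequence("t", "a" * 10), grp)
        assert cons.labels == common


class TestFeasibility:
    def test_generating_labelling_is_feasible(self, toy):
        seq, path = sample_sequence(toy, 80, seed=21)
        from kbestpaths import labelling_of

        assert labelling_feasible(toy, seq, labelling_of(toy, path))

    def test_one_residue_helix_is_infeasible(self, toy):
        # the membrane model's helices have minimum length 4
        labels = "i" * 10 + "M" + "o" * 9
        seq, _ = sample_sequence(toy, 20, seed=22)
        assert not labelling_feasible(toy, seq, labels)


class TestConfidence:
    def test_exhaustive_k_fills_the_top_band(self, two_state):
        seq = Sequence("t", "xyzx")
        res = kbest_naive(two_state, seq, 100)
        rep = confidence_report(two_state, seq, res)
        assert rep.total_conditional_prob == pytest.approx(1.0, abs=1e-9)
        assert rep.band == "0.5 - 1"
        assert rep.helix_counts_agree  # no membrane label at all: all zero helices

    def test_bands_partition_the_unit_interval(self):
        assert probability_band(0.0) == "< 0.01"
        assert probability_band(0.009999) == "< 0.01"
        assert probability_band(0.01) == "0.01 - 0.5"
        assert probability_band(0.4999) == "0.01 - 0.5"
        assert probability_band(0.5) == "0.5 - 1"
        assert probability_band(1.0) == "0.5 - 1"

    def test_group_table_matches_groups(self, toy):
        seq, _ = sample_sequence(toy, 80, seed=30)
        res = kbest_naive(toy, seq, 20)
        rep = confidence_report(toy, seq, res)
        assert len(rep.group_table) == len(rep.groups)
        assert rep.group_table["weight"].sum() == pytest.approx(
            rep.total_conditional_prob, abs=1e-9
        )


class TestTopGroups:
    def test_mirror_fixture_yields_opposite_sided_pair(self, mirror):
        seq, _ = sample_sequence(mirror, 40, seed=41)
        res = kbest_naive(mirror, seq, 32)
        groups = group_paths(mirror, seq, res)
        pair = top_groups(groups, g=2)
        assert not pair.fewer_than_requested
        (g1, c1), (g2, c2) = pair.pairs
        assert g1.topology_key[0] == g2.topology_key[0]
        assert {g1.topology_key[1], g2.topology_key[1]} == {"i", "o"}
        assert g1.weight == pytest.approx(g2.weight, abs=1e-9)
        assert topology_of(c1.labels).sidedness != topology_of(c2.labels).sidedness

    def test_single_group_flagged_when_two_requested(self, chain):
        res = kbest_naive(chain, Sequence("t", "uuuu"), 5)
        groups = group_paths(chain, Sequence("t", "uuuu"), res, membrane_label="M")
        out = top_groups(groups, g=2)
        assert out.fewer_than_requested
        assert len(out.pairs) == 1

    def test_g1_is_the_heaviest_group_with_its_consensus(self, toy):
        seq, _ = sample_sequence(toy, 60, seed=55)
        groups = group_paths(toy, seq, kbest_naive(toy, seq, 10))
        out = top_groups(groups, g=1)
        assert out.pairs[0][0] is heaviest_group(groups)
        assert out.pairs[0][1].labels == consensus_boundary_average(groups[0]).labels


def _two_label_hmm() -> Hmm:
    """Tiny i/o-labelled model over a 2-symbol alphabet."""
    return Hmm.from_tables(
        states=["P", "Q"],
        start_state="I",
        alphabet=["a", "b"],
        transitions={
            ("I", "P"): 0.8,
            ("I", "Q"): 0.2,
            ("P", "P"): 0.7,
            ("P", "Q"): 0.3,
            ("Q", "Q"): 0.6,
            ("Q", "P"): 0.4,
        },
        emissions={("P", "a"): 0.9, ("P", "b"): 0.1, ("Q", "a"): 0.2, ("Q", "b"): 0.8},
        labels={"P": "i", "Q": "o"},
    )
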