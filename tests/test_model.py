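"""Model validation, path scoring, forward algorithm and 1-best decoding."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from kbestpaths import (
    Hmm,
    Sequence,
    forward_log_prob,
    path_log_prob,
    validate,
    viterbi,
)
from kbestpaths.model import NEG_INF

from conftest import enumerate_paths, random_instance


def make_hmm(**overrides):
    base = dict(
        states=["A", "B"],
        start_state="I",
        alphabet=["x", "y"],
        transitions={
            ("I", "A"): 1.0,
            ("A", "A"): 0.5,
            ("A", "B"): 0.5,
            ("B", "B"): 1.0,
        },
        emissions={("A", "x"): 1.0, ("B", "y"): 1.0},
        labels={"A": "a", "B": "b"},
    )
    base.update(overrides)
    return Hmm.from_tables(**base)


class TestValidate:
    def test_well_formed_model_has_no_violations(self, toy):
        assert validate(toy) == []
        assert validate(make_hmm()) == []

    def test_transition_row_not_summing_to_one_names_the_state(self):
        h = make_hmm(
            transitions={("I", "A"): 1.0, ("A", "A"): 0.5, ("A", "B"): 0.4, ("B", "B"): 1.0}
        )
        problems = validate(h)
        assert len(problems) == 1 and "'A'" in problems[0]

    def test_incoming_edge_to_start_state_is_a_violation(self):
        h = make_hmm(
            transitions={
                ("I", "A"): 1.0,
                ("A", "A"): 0.5,
                ("A", "B"): 0.5,
                ("B", "B"): 0.5,
                ("B", "I"): 0.5,
            }
        )
        problems = validate(h)
        assert any("incoming" in p for p in problems)

    def test_unreachable_state_is_a_violation(self):
        h = make_hmm(
            transitions={("I", "A"): 1.0, ("A", "A"): 1.0, ("B", "B"): 1.0},
        )
        problems = validate(h)
        assert any("reachable" in p and "'B'" in p for p in problems)


class TestPathLogProb:
    def test_all_unit_factors_score_zero(self):
        h = Hmm.from_tables(
            states=["A"],
            start_state="I",
            alphabet=["s"],
            transitions={("I", "A"): 1.0, ("A", "A"): 1.0},
            emissions={("A", "s"): 1.0},
            labels={"A": "a"},
        )
        assert path_log_prob(h, Sequence("t", "sss"), ["A", "A", "A"]) == 0.0

    def test_forbidden_transition_scores_minus_infinity(self):
        h = make_hmm()
        # B -> A has probability zero
        assert path_log_prob(h, Sequence("t", "xyx"), ["A", "B", "A"]) == NEG_INF

    def test_matches_hand_product_of_factors(self, two_state):
        # independent scalar recomputation of P(AAB emits "xyz")
        expected = math.log(0.7 * 0.5) + math.log(0.6 * 0.3) + math.log(0.4 * 0.7)
        got = path_log_prob(two_state, Sequence("t", "xyz"), ["A", "A", "B"])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_raises(self, two_state):
        with pytest.raises(ValueError, match="length"):
            path_log_prob(two_state, Sequence("t", "xy"), ["A"])


class TestForward:
    def test_deterministic_model_equals_its_single_path(self, chain):
        seq = Sequence("t", "uuuu")
        assert forward_log_prob(chain, seq) == pytest.approx(
            path_log_prob(chain, seq, ["C1", "C2", "C1", "C2"]), abs=1e-12
        )

    @pytest.mark.parametrize("trial", range(20))
    def test_equals_logsumexp_over_enumerated_paths(self, trial):
        rng = np.random.default_rng(500 + trial)
        hmm, seq, _ = random_instance(rng, max_m=4, max_n=8)
        enum = enumerate_paths(hmm, seq)
        assert forward_log_prob(hmm, seq) == pytest.approx(
            logsumexp([s for s, _ in enum]), abs=1e-9
        )
        # total probability is a proper probability
        assert 0.0 < math.exp(forward_log_prob(hmm, seq)) <= 1.0 + 1e-12

    def test_dominates_every_single_path(self, two_state):
        seq = Sequence("t", "xyzz")
        fw = forward_log_prob(two_state, seq)
        for _, path in enumerate_paths(two_state, seq)[:10]:
            states = [two_state.states[i] for i in path]
            assert fw >= path_log_prob(two_state, seq, states)

    def test_unknown_symbol_raises(self, two_state):
        with pytest.raises(ValueError, match="symbol"):
            forward_log_prob(two_state, Sequence("t", "xq"))


class TestViterbi:
    def test_deterministic_single_path_model(self, chain):
        best = viterbi(chain, Sequence("t", "uuu"))
        assert best.states == ("C1", "C2", "C1")
        assert best.rank == 1

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_enumeration_argmax(self, trial):
        rng = np.random.default_rng(900 + trial)
        hmm, seq, _ = random_instance(rng, max_m=4, max_n=8)
        best = viterbi(hmm, seq)
        top_score, top_path = enumerate_paths(hmm, seq)[0]
        assert best.log_joint == pytest.approx(top_score, abs=1e-9)
        assert tuple(hmm.state_index[s] for s in best.states) == top_path
        # round-trip: the reported score recomputes from the path itself
        assert path_log_prob(hmm, seq, list(best.states)) == pytest.approx(
            best.log_joint, abs=1e-12
        )

    def test_no_positive_path_returns_none(self):
        h = make_hmm()
        # "A" can only emit x at position 1; sequence starting with y is impossible
        assert viterbi(h, Sequence("t", "yx")) is None


def test_state_order_permutation_leaves_probabilities_unchanged(two_state):
    permuted = Hmm.from_tables(
        states=["B", "A"],
        start_state="I",
        alphabet=["x", "y", "z"],
        transitions={
            ("I", "A"): 0.7,
            ("I", "B"): 0.3,
            ("A", "A"): 0.6,
            ("A", "B"): 0.4,
            ("B", "A"): 0.5,
            ("B", "B"): 0.5,
        },
        emissions={
            ("A", "x"): 0.5,
            ("A", "y"): 0.3,
            ("A", "z"): 0.2,
            ("B", "x"): 0.1,
            ("B", "y"): 0.2,
            ("B", "z"): 0.7,
        },
        labels={"A": "a", "B": "b"},
    )
    seq = Sequence("t", "xyzzy")
    assert forward_log_prob(two_state, seq) == pytest.approx(
        forward_log_prob(permuted, seq), abs=1e-12
    )
    for path in (["A", "A", "B", "B", "A"], ["B", "B", "B", "A", "A"]):
        assert path_log_prob(two_state, seq, path) == pytest.approx(
            path_log_prob(permuted, seq, path), abs=1e-12
        )
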