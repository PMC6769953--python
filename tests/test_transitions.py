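"""Transition counts, stationary distributions, standardized entropy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialgaze.aoi import OFFSCREEN
from socialgaze.errors import DataError
from socialgaze.transitions import (
    TransitionMatrix,
    build_transition_matrix,
    first_transition_probability,
    normalized_entropy,
    stationary_distribution,
)

from test_aoi import seq_from_labels


def matrix_from_probs(p, counts_scale=1000):
    """TransitionMatrix with counts proportional to a probability matrix."""
    p = np.asarray(p, dtype=float)
    states = tuple(chr(ord("A") + i) for i in range(len(p)))
    return TransitionMatrix(states, np.round(p * counts_scale).astype(int))


class TestBuildTransitionMatrix:
    def test_simple_sequence_counts(self):
        m = build_transition_matrix(seq_from_labels(["A", "B", "A", "C"]), ["A", "B", "C"])
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 1  # A -> B
        expected[1, 0] = 1  # B -> A
        expected[0, 2] = 1  # A -> C
        assert np.array_equal(m.counts, expected)

    def test_pooling_does_not_bridge_sequences(self):
        s1 = seq_from_labels(["A", "B"])
        s2 = seq_from_labels(["C", "A"])
        m = build_transition_matrix([s1, s2], ["A", "B", "C"])
        assert m.n_transitions == 2
        assert m.counts[1, 2] == 0  # no B -> C bridge

    def test_offscreen_removal_recollapses(self):
        seq = seq_from_labels(["A", OFFSCREEN, "A", "B"])
        m = build_transition_matrix(seq, ["A", "B"], include_offscreen=False)
        # A -Offscreen- A merges; only A -> B remains
        assert m.n_transitions == 1
        assert m.counts[0, 1] == 1

    def test_label_outside_states_is_error(self):
        with pytest.raises(DataError):
            build_transition_matrix(seq_from_labels(["A", "Z"]), ["A", "B"])

    @given(
        labels=st.lists(st.sampled_from("ABCD"), min_size=2, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_counts_equal_exhaustive_pair_enumeration(self, labels):
        collapsed = [l for i, l in enumerate(labels) if i == 0 or l != labels[i - 1]]
        if len(collapsed) < 2:
            return
        m = build_transition_matrix(seq_from_labels(collapsed), list("ABCD"))
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                expected = sum(
                    1 for x, y in zip(collapsed, collapsed[1:]) if (x, y) == (a, b)
                )
                assert m.counts[i, j] == expected


class TestStationaryDistribution:
    def test_symmetric_swap_is_half_half(self):
        m = matrix_from_probs([[0, 1], [1, 0]])
        assert stationary_distribution(m) == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_two_state_balance_equations(self):
        # pi solves pi P = pi for P = [[0.5, 0.5], [1, 0]]: hand solution
        # pi_A = pi_A/2 + pi_B, pi_A + pi_B = 1 -> pi = (2/3, 1/3)
        m = matrix_from_probs([[0.5, 0.5], [1.0, 0.0]])
        assert stationary_distribution(m) == pytest.approx([2 / 3, 1 / 3], abs=1e-9)

    def test_fixed_point_under_multiplication(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 30, (4, 4))
        np.fill_diagonal(counts, 0)
        m = TransitionMatrix(tuple("ABCD"), counts)
        pi = stationary_distribution(m)
        assert pi @ m.probabilities == pytest.approx(pi, abs=1e-8)

    def test_empty_matrix_is_error(self):
        m = TransitionMatrix(("A", "B"), np.zeros((2, 2), dtype=int))
        with pytest.raises(DataError):
            stationary_distribution(m)

    def test_reducible_chain_falls_back_to_visit_frequencies(self):
        # A -> B only: B has no outgoing transitions
        counts = np.array([[0, 3], [0, 0]])
        m = TransitionMatrix(("A", "B"), counts)
        pi = stationary_distribution(m)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()


class TestNormalizedEntropy:
    def test_uniform_rows_give_maximum_entropy(self):
        p = np.full((3, 3), 1 / 3)
        m = matrix_from_probs(p, counts_scale=999)
        assert normalized_entropy(m) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_cycle_gives_zero(self):
        m = matrix_from_probs([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert normalized_entropy(m) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_state_case(self):
        # P = [[0.5, 0.5], [1, 0]], pi = (2/3, 1/3):
        # H = 2/3 * 1 bit + 1/3 * 0 = 2/3; H_norm = (2/3) / log2(2) = 2/3
        m = matrix_from_probs([[0.5, 0.5], [1.0, 0.0]])
        assert normalized_entropy(m) == pytest.approx(2 / 3, abs=1e-9)

    def test_single_visited_state_is_undefined(self):
        m = TransitionMatrix(("A", "B"), np.zeros((2, 2), dtype=int))
        with pytest.raises(DataError):
            normalized_entropy(m)

    @given(
        seed=st.integers(0, 2**16), n=st.integers(2, 5)
    )
    @settings(max_examples=100, deadline=None)
    def test_entropy_bounded_and_permutation_invariant(self, seed, n):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, (n, n))
        np.fill_diagonal(counts, 0)
        m = TransitionMatrix(tuple("ABCDE"[:n]), counts)
        try:
            h = normalized_entropy(m)
        except DataError:
            return
        assert 0.0 <= h <= 1.0 + 1e-12
        perm = rng.permutation(n)
        m_perm = TransitionMatrix(
            tuple(np.array(m.states)[perm]), counts[np.ix_(perm, perm)]
        )
        assert normalized_entropy(m_perm) == pytest.approx(h, abs=1e-9)

    def test_merging_copies_leaves_entropy_unchanged(self):
        seq = seq_from_labels(["A", "B", "C", "A", "B"])
        m1 = build_transition_matrix(seq, ["A", "B", "C"])
        m3 = build_transition_matrix([seq, seq, seq], ["A", "B", "C"])
        assert np.array_equal(m3.counts, 3 * m1.counts)
        assert normalized_entropy(m3) == pytest.approx(normalized_entropy(m1))

    def test_maximum_only_for_uniform_rows(self):
        m = matrix_from_probs([[0, 0.7, 0.3], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        assert normalized_entropy(m) < 1.0


class TestFirstTransition:
    targets = {"group": {"Gatekeeper", "GroupMemberA", "GroupMemberB"},
               "excluded": {"Excluded"}}

    def test_first_target_after_source(self):
        seq = seq_from_labels(["Neutral", "GroupMemberA", "Excluded"])
        frame = first_transition_probability(
            [("i1", seq)], "Neutral", self.targets, window=(0, 10_000)
        )
        assert frame.loc[0, "first_direction"] == "group"

    def test_offscreen_skipped_first_onscreen_target_wins(self):
        seq = seq_from_labels(["Neutral", OFFSCREEN, "Excluded"])
        frame = first_transition_probability(
            [("i1", seq)], "Neutral", self.targets, window=(0, 10_000)
        )
        assert frame.loc[0, "first_direction"] == "excluded"

    def test_source_never_visited_flags_no_expectation(self):
        seq = seq_from_labels(["Excluded", "GroupMemberA"])
        frame = first_transition_probability(
            [("i1", seq)], "Neutral", self.targets, window=(0, 10_000)
        )
        assert frame.loc[0, "first_direction"] == "no_expectation"

    def test_pooled_probabilities_equal_matrix_row_sums(self):
        seqs = [
            ("i1", seq_from_labels(["Neutral", "GroupMemberA", "Neutral", "Excluded"])),
            ("i2", seq_from_labels(["Neutral", "Excluded", "Neutral", "Gatekeeper"])),
        ]
        frame = first_transition_probability(
            seqs, "Neutral", self.targets, window=(0, 60_000)
        )
        m = build_transition_matrix(
            [s for _, s in seqs], ["Neutral", "GroupMemberA", "Gatekeeper", "Excluded"]
        )
        row = m.probabilities[m.states.index("Neutral")]
        expected_group = sum(
            row[m.states.index(t)]
            for t in ("Gatekeeper", "GroupMemberA", "GroupMemberB")
            if t in m.states
        )
        assert frame.attrs["pooled"]["group"] == pytest.approx(expected_group)
        assert frame.attrs["pooled"]["excluded"] == pytest.approx(
            row[m.states.index("Excluded")]
        )
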