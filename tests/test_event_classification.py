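import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from porestate import event_classification as ec
from porestate import state_graph as sg


def _graph_from_counts(spec):
    """Build a StateGraph whose node probabilities follow ``spec``.

    ``spec`` maps state label -> number of frames; frame order interleaves
    so probabilities are exact.
    """
    seq = []
    for label, n in spec.items():
        seq.extend([label] * n)
    return sg.build_graph(seq)


class TestScoreMatrix:
    def test_three_point_rule(self):
        m = ec.make_score_matrix(["K:0:2:4", "K:0:2:5", "K:0:2:4:6"])
        assert m.score("K:0:2:4", "K:0:2:4") == 1.0
        assert m.score("K:0:2:4", "K:0:2:5") == 0.5
        assert m.score("K:0:2:4", "K:0:2:4:6") == 0.0

    def test_symmetric_with_unit_diagonal(self):
        labels = ["K:0", "K:1", "K:0:1", "K:", "K:0:2:4"]
        m = ec.make_score_matrix(labels)
        np.testing.assert_array_equal(m.matrix, m.matrix.T)
        np.testing.assert_array_equal(np.diag(m.matrix), 1.0)
        assert set(np.unique(m.matrix)) <= {0.0, 0.5, 1.0}


class TestCharacterMap:
    def _graph(self):
        return _graph_from_counts(
            {
                "K:0:2:4": 50,  # anchor, 3 ions
                "K:1:3:5": 20,  # 3 ions -> 'A'
                "K:2:4:6": 10,  # 3 ions -> 'B'
                "K:0:2:4:6": 15,  # 4 ions -> 'a'
                "K:0:2:4:5": 5,  # 4 ions -> 'b'
                "K:0:2:3:4:6": 3,  # 5 ions -> '#'
                "K:2:4": 2,  # 2 ions -> pool
            }
        )

    def test_class_assignment(self):
        cmap = ec.assign_characters(self._graph())
        assert cmap.to_char["K:0:2:4"] == "*"
        assert cmap.to_char["K:1:3:5"] == "A"
        assert cmap.to_char["K:2:4:6"] == "B"
        assert cmap.to_char["K:0:2:4:6"] == "a"
        assert cmap.to_char["K:0:2:4:5"] == "b"
        assert cmap.to_char["K:0:2:3:4:6"] == "#"
        assert cmap.to_char["K:2:4"] == "0"

    def test_bijection(self):
        cmap = ec.assign_characters(self._graph())
        for state, ch in cmap.to_char.items():
            assert cmap.to_state[ch] == state

    def test_deterministic_given_probabilities(self):
        a = ec.assign_characters(self._graph())
        b = ec.assign_characters(self._graph())
        assert a.to_char == b.to_char

    def test_restrict_to_subset(self):
        g = self._graph()
        cmap = ec.assign_characters(g, restrict_to={"K:1:3:5"})
        assert set(cmap.to_char) == {"K:0:2:4", "K:1:3:5"}


class TestCycleToSequence:
    def test_explicit_and_compact_forms(self):
        cmap = ec.assign_characters(
            _graph_from_counts({"K:0:2:4": 5, "K:0:2:4:6": 2, "K:0:2:4:5": 1})
        )
        cycle = ["K:0:2:4", "K:0:2:4:6", "K:0:2:4:5", "K:0:2:4"]
        assert ec.cycle_to_sequence(cycle, cmap) == "*ab*"
        assert ec.cycle_to_sequence(cycle, cmap, compact=True) == "ab*"

    def test_empty_interior(self):
        cmap = ec.assign_characters(_graph_from_counts({"K:0:2:4": 2}))
        assert ec.cycle_to_sequence(["K:0:2:4", "K:0:2:4"], cmap) == "**"

    def test_round_trip_to_states(self):
        cmap = ec.assign_characters(
            _graph_from_counts({"K:0:2:4": 5, "K:0:2:4:6": 2, "K:2:4": 1})
        )
        cycle = ["K:0:2:4", "K:0:2:4:6", "K:2:4", "K:0:2:4"]
        assert cmap.decode(ec.cycle_to_sequence(cycle, cmap)) == cycle

    def test_unmapped_state_is_error(self):
        cmap = ec.assign_characters(_graph_from_counts({"K:0:2:4": 2}))
        with pytest.raises(KeyError):
            ec.cycle_to_sequence(["K:0:2:4", "K:9"], cmap)


def _random_matrix_and_sequences(rng, n_pairs, max_len=6):
    """Score matrix over 5 symbols spanning all three score levels."""
    states = ["K:0:2:4", "K:1:3:5", "K:2:4:6", "K:0:2:4:6", "K:2:4"]
    chars = "ABCDE"
    counts = [3, 3, 3, 4, 2]
    mat = np.where(np.equal.outer(counts, counts), 0.5, 0.0)
    np.fill_diagonal(mat, 1.0)
    scores = ec.ScoreMatrix(symbols=list(chars), matrix=mat)
    pairs = []
    for _ in range(n_pairs):
        a = "".join(rng.choice(list(chars), rng.integers(1, max_len + 1)))
        b = "".join(rng.choice(list(chars), rng.integers(1, max_len + 1)))
        pairs.append((a, b))
    return scores, pairs


class TestAlign:
    def test_self_alignment_is_length(self):
        scores = ec.make_score_matrix(["K:0", "K:1", "K:0:1"])
        seq = ["K:0", "K:1", "K:0:1", "K:0", "K:0:1"]
        assert ec.align(seq, seq, scores).score == pytest.approx(5.0)

    def test_known_alignment(self):
        scores, _ = _random_matrix_and_sequences(np.random.default_rng(0), 0)
        res = ec.align("AAB", "AB", scores)
        assert res.score == pytest.approx(2.0)
        assert len(res.aligned_a) == len(res.aligned_b)
        assert res.aligned_a.replace("-", "") == "AAB"
        assert res.aligned_b.replace("-", "") == "AB"

    @pytest.mark.parametrize("gap", [0.0, -0.2])
    def test_matches_brute_force(self, rng, gap):
        scores, pairs = _random_matrix_and_sequences(rng, 60)
        for a, b in pairs:
            dp = ec.align(a, b, scores, gap).score
            brute = ec.brute_force_align_score(a, b, scores, gap)
            assert dp == pytest.approx(brute, abs=1e-9)

    def test_symmetry(self, rng):
        scores, pairs = _random_matrix_and_sequences(rng, 30)
        for a, b in pairs:
            assert ec.align(a, b, scores).score == pytest.approx(
                ec.align(b, a, scores).score
            )

    def test_score_bounded_by_min_length_at_zero_gap(self, rng):
        scores, pairs = _random_matrix_and_sequences(rng, 30)
        for a, b in pairs:
            assert ec.align(a, b, scores).score <= min(len(a), len(b)) + 1e-12

    def test_unknown_symbol_is_error(self):
        scores = ec.make_score_matrix(["K:0"])
        with pytest.raises(KeyError):
            ec.align(["K:0"], ["K:9"], scores)


class TestEventSimilarity:
    def test_identical_events_score_one(self):
        scores = ec.make_score_matrix(["K:0", "K:1"])
        sim = ec.event_similarity([["K:0", "K:1"], ["K:0", "K:1"]], scores)
        assert sim[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal_in_range(self, rng):
        scores, pairs = _random_matrix_and_sequences(rng, 10)
        events = [a for a, _ in pairs]
        sim = ec.event_similarity(events, scores)
        np.testing.assert_array_equal(sim, sim.T)
        np.testing.assert_array_equal(np.diag(sim), 1.0)
        assert (sim >= 0).all() and (sim <= 1).all()


class TestClusterEvents:
    def test_identical_pair_merges_first_at_zero(self):
        sim = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        res = ec.cluster_events(sim)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_upgma_heights_monotone(self, rng):
        scores, pairs = _random_matrix_and_sequences(rng, 8)
        sim = ec.event_similarity([a for a, _ in pairs], scores)
        res = ec.cluster_events(sim)
        heights = res.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_four_event_hand_traced_upgma(self):
        """Distances chosen so the UPGMA merge order and heights are
        hand-computable: (0,1)@0.1, (2,3)@0.2, then the two pairs at the
        mean of the four cross distances = 0.875."""
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.95],
                [0.1, 0.0, 0.8, 0.85],
                [0.9, 0.8, 0.0, 0.2],
                [0.95, 0.85, 0.2, 0.0],
            ]
        )
        res = ec.cluster_events(1.0 - d)
        Z = res.linkage_matrix
        assert set(Z[0, :2].astype(int)) == {0, 1} and Z[0, 2] == pytest.approx(0.1)
        assert set(Z[1, :2].astype(int)) == {2, 3} and Z[1, 2] == pytest.approx(0.2)
        assert Z[2, 2] == pytest.approx(0.875)

    def test_midpoint_cut_two_blocks(self):
        sim = np.array(
            [
                [1.0, 0.9, 0.1, 0.1],
                [0.9, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.9],
                [0.1, 0.1, 0.9, 1.0],
            ]
        )
        res = ec.cluster_events(sim, labels=list("abcd"))
        flat = res.midpoint_cut()
        assert flat[0] == flat[1] and flat[2] == flat[3] and flat[0] != flat[2]

    def test_newick_parses_with_independent_library(self):
        import dendropy

        sim = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]])
        res = ec.cluster_events(sim, labels=["e0", "e1", "e2"])
        tree = dendropy.Tree.get(data=res.to_newick(), schema="newick")
        assert {t.label for t in tree.taxon_namespace} == {"e0", "e1", "e2"}

    def test_asymmetric_input_rejected(self):
        sim = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ec.cluster_events(sim)
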