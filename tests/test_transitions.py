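import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeflow.errors import ArgumentError, IntegrityError
from gazeflow.transitions import (
    count_transitions,
    flat_support,
    hellinger,
    hellinger_from_probs,
    normalized_by_max,
    rowwise_hellinger,
    to_distribution,
    to_markov,
    TransitionDistribution,
)
from oracles import count_pairs_oracle, hellinger_oracle

ABC = ("A", "B", "C")


def dist(probs, labels=("A", "B")):
    return TransitionDistribution(
        support=flat_support(labels)[: len(probs)]
        if len(probs) != len(labels) ** 2
        else flat_support(labels),
        probabilities=np.asarray(probs, dtype=float),
    )


class TestCountTransitions:
    def test_definition_example(self):
        m = count_transitions([["A", "A", "B", "C", "A"]], ABC)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 0] = 1  # A->A
        expected[0, 1] = 1  # A->B
        expected[1, 2] = 1  # B->C
        expected[2, 0] = 1  # C->A
        assert (m.counts == expected).all()
        assert m.n_transitions == 4

    def test_single_fixation_sequence(self):
        m = count_transitions([["A"]], ABC)
        assert m.n_transitions == 0
        assert (m.counts == 0).all()

    def test_two_sequences_pool(self):
        m = count_transitions([["A", "B"], ["B", "A"]], ABC)
        assert m.counts[0, 1] == 1 and m.counts[1, 0] == 1
        assert m.n_transitions == 2
        assert m.n_sequences == 2

    def test_label_outside_support(self):
        with pytest.raises(IntegrityError):
            count_transitions([["A", "Z"]], ABC)

    @settings(max_examples=30, deadline=None)
    @given(
        seqs=st.lists(
            st.lists(st.sampled_from(ABC), min_size=1, max_size=12),
            min_size=1, max_size=6,
        )
    )
    def test_conserves_transitions_and_matches_oracle(self, seqs):
        m = count_transitions(seqs, ABC)
        assert m.n_transitions == sum(len(s) - 1 for s in seqs)
        oracle = count_pairs_oracle(seqs)
        for i, a in enumerate(ABC):
            for j, b in enumerate(ABC):
                assert m.counts[i, j] == oracle.get((a, b), 0)

    @settings(max_examples=20, deadline=None)
    @given(
        seqs=st.lists(
            st.lists(st.sampled_from(ABC), min_size=2, max_size=8),
            min_size=2, max_size=5,
        ),
        seed=st.integers(0, 100),
    )
    def test_pooling_is_order_free(self, seqs, seed):
        shuffled = list(seqs)
        np.random.default_rng(seed).shuffle(shuffled)
        a = to_distribution(count_transitions(seqs, ABC))
        b = to_distribution(count_transitions(shuffled, ABC))
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestToMarkov:
    def test_row_normalization(self):
        m = count_transitions([["A", "B"], ["A", "B"], ["A", "C"], ["A", "C"]], ABC)
        chain = to_markov(m)
        np.testing.assert_allclose(chain.matrix[0], [0.0, 0.5, 0.5])
        assert set(chain.zero_rows) == {"B", "C"}

    def test_identity_pattern(self):
        m = count_transitions([["A", "A"], ["B", "B"], ["C", "C"]], ABC)
        chain = to_markov(m)
        np.testing.assert_array_equal(chain.matrix, np.eye(3))

    def test_zero_total_is_error(self):
        with pytest.raises(ArgumentError):
            to_markov(count_transitions([["A"]], ABC))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_one_or_zero(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            [ABC[i] for i in rng.integers(0, 3, size=rng.integers(2, 10))]
            for _ in range(3)
        ]
        chain = to_markov(count_transitions(seqs, ABC))
        sums = chain.matrix.sum(axis=1)
        for lab, s in zip(chain.labels, sums):
            if lab in chain.zero_rows:
                assert s == 0.0
            else:
                assert s == pytest.approx(1.0)


class TestToDistribution:
    def test_flattening_example(self):
        m = count_transitions([["A", "B"]] * 3 + [["B", "A"]], ("A", "B"))
        d = to_distribution(m)
        assert d.support == (("A", "A"), ("A", "B"), ("B", "A"), ("B", "B"))
        np.testing.assert_allclose(d.probabilities, [0.0, 0.75, 0.25, 0.0])

    def test_degenerate_mass(self):
        d = to_distribution(count_transitions([["A", "A"]], ("A", "B")))
        assert d.probabilities[0] == 1.0
        assert d.probabilities.sum() == 1.0

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_total_mass_is_one(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            [ABC[i] for i in rng.integers(0, 3, size=rng.integers(2, 15))]
            for _ in range(4)
        ]
        d = to_distribution(count_transitions(seqs, ABC))
        assert d.probabilities.sum() == pytest.approx(1.0)


class TestHellinger:
    def test_identical_is_zero(self):
        p = dist([0.25, 0.25, 0.25, 0.25])
        assert hellinger(p, p) == 0.0

    def test_disjoint_is_one(self):
        support = flat_support(("A", "B"))[:2]
        p = TransitionDistribution(support, np.array([1.0, 0.0]))
        q = TransitionDistribution(support, np.array([0.0, 1.0]))
        assert hellinger(p, q) == pytest.approx(1.0, abs=1e-15)

    def test_known_value(self):
        support = flat_support(("A", "B"))[:2]
        p = TransitionDistribution(support, np.array([0.5, 0.5]))
        q = TransitionDistribution(support, np.array([0.25, 0.75]))
        h = hellinger(p, q)
        assert h == pytest.approx(0.18459, abs=5e-6)
        assert h == pytest.approx(hellinger_oracle([0.5, 0.5], [0.25, 0.75]),
                                  abs=1e-14)

    def test_mismatched_support_is_error(self):
        p = TransitionDistribution(flat_support(("A", "B"))[:2],
                                   np.array([0.5, 0.5]))
        q = TransitionDistribution(flat_support(("A", "C"))[:2],
                                   np.array([0.5, 0.5]))
        with pytest.raises(ArgumentError):
            hellinger(p, q)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 10))
        p, q = rng.dirichlet(np.ones(k)), rng.dirichlet(np.ones(k))
        h = hellinger_from_probs(p, q)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(hellinger_from_probs(q, p), abs=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        p, q, r = (rng.dirichlet(np.ones(k)) for _ in range(3))
        assert hellinger_from_probs(p, r) <= (
            hellinger_from_probs(p, q) + hellinger_from_probs(q, r) + 1e-12
        )


def test_rowwise_mode_zero_for_identical_chains():
    m = count_transitions([["A", "B", "A", "C", "A"]], ABC)
    chain = to_markov(m)
    assert rowwise_hellinger(chain, chain) == 0.0


def test_normalized_by_max():
    m = count_transitions([["A", "B"], ["A", "B"], ["A", "C"]], ABC)
    scaled = normalized_by_max(m)
    assert scaled.max() == 1.0
    assert scaled[0, 2] == pytest.approx(0.5)
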