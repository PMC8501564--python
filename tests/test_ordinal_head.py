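import itertools
import math

import numpy as np
import pytest

from orrcnn.data_io import ScoredPair
from orrcnn.encoder import RCNNConfig
from orrcnn.ordinal_head import (
    IntervalPartition,
    MLPParams,
    OrdinalModel,
    RegressionHead,
    SubClassifier,
    aggregate_rank,
    assign_labels,
    call_ppi,
    cross_entropy_loss,
    decide_fk,
    label_of_score,
    relabel_for_k,
    score_from_rank,
    subclassifier_forward,
)

from .conftest import labeled_pairs
from .oracles import rank_by_enumeration, two_term_cross_entropy


class TestLabelOfScore:
    @pytest.mark.parametrize("score,expected", [(0.72, 15), (0.05, 2), (0.03, 1), (0.999, 20)])
    def test_k20_unit_interval(self, score, expected, partition20):
        assert label_of_score(score, partition20) == expected

    @pytest.mark.parametrize("score", [0.0, 1.0, -0.1, 1.5])
    def test_outside_open_range_rejected(self, score, partition20):
        with pytest.raises(ValueError):
            label_of_score(score, partition20)

    def test_boundary_belongs_to_right_interval(self):
        p = IntervalPartition(0.0, 1.0, 4)
        assert label_of_score(0.25, p) == 2
        assert label_of_score(0.2499999, p) == 1


class TestRelabel:
    def test_partition_conservation_all_k(self, partition20, rng):
        pairs = labeled_pairs(rng.uniform(0.01, 0.99, size=200), partition20)
        for k in range(1, 20):
            pos, neg = relabel_for_k(pairs, k, 20)
            assert len(pos) + len(neg) == len(pairs)

    def test_top_k_positives_are_label_K(self, partition20, rng):
        pairs = labeled_pairs(rng.uniform(0.01, 0.99, size=300), partition20)
        pos, _ = relabel_for_k(pairs, 19, 20)
        assert all(p.label == 20 for p in pos)

    def test_monotone_inclusion(self, partition20, rng):
        pairs = labeled_pairs(rng.uniform(0.01, 0.99, size=150), partition20)
        prev = None
        for k in range(1, 20):
            pos, _ = relabel_for_k(pairs, k, 20)
            ids = {id(p) for p in pos}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            relabel_for_k([ScoredPair("a", "b", 0.5)], 1, 20)


class TestSubClassifier:
    def make(self, rng, in_dim=6):
        return SubClassifier(index=1, mlp=MLPParams.init(rng, in_dim, 8, 2))

    def test_softmax_normalised(self, rng):
        c = self.make(rng)
        x = rng.normal(size=(40, 6))
        s1, s2 = subclassifier_forward(x, c)
        np.testing.assert_allclose(s1 + s2, 1.0, atol=1e-9)
        assert (s1 > 0).all() and (s2 > 0).all()

    def test_symmetric_logits_give_half(self, rng):
        c = self.make(rng)
        c.mlp.W2.data[:] = 0.0
        c.mlp.b2.data[:] = 0.0
        s1, s2 = subclassifier_forward(rng.normal(size=6), c)
        assert s1 == pytest.approx(0.5) and s2 == pytest.approx(0.5)

    def test_softmax_limit(self, rng):
        c = self.make(rng)
        c.mlp.W2.data[:] = 0.0
        c.mlp.b2.data[:] = [40.0, -40.0]
        s1, _ = subclassifier_forward(rng.normal(size=6), c)
        assert s1 == pytest.approx(1.0, abs=1e-12)

    def test_matches_two_term_softmax_formula(self, rng):
        c = self.make(rng)
        x = rng.normal(size=6)
        logits = c.logits(x[None, :])[0]
        s1, s2 = subclassifier_forward(x, c)
        expected1 = math.exp(logits[0]) / (math.exp(logits[0]) + math.exp(logits[1]))
        assert s1 == pytest.approx(expected1, rel=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            subclassifier_forward(rng.normal(size=4), self.make(rng, in_dim=6))


class TestDecideFk:
    @pytest.mark.parametrize(
        "s1,s2,expected", [(0.6, 0.4, 1), (0.5, 0.5, -1), (0.4999, 0.5001, -1)]
    )
    def test_rule(self, s1, s2, expected):
        assert decide_fk(s1, s2) == expected


class TestAggregateRank:
    @pytest.mark.parametrize(
        "decisions,expected",
        [([-1] * 19, 1), ([1] * 19, 20), ([1, -1, 1], 3)],
    )
    def test_examples(self, decisions, expected):
        assert aggregate_rank(decisions) == expected

    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    def test_exhaustive_enumeration(self, K):
        for decisions in itertools.product((-1, 1), repeat=K - 1):
            assert aggregate_rank(list(decisions)) == rank_by_enumeration(decisions)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rank([1, 0, -1])


class TestScoreFromRank:
    def test_mid_left_right_k20(self, partition20):
        assert score_from_rank(1, partition20, "mid") == pytest.approx(0.025)
        assert score_from_rank(5, partition20, "left") == pytest.approx(0.20)
        assert score_from_rank(5, partition20, "right") == pytest.approx(0.25)

    def test_ordering_and_widths(self, partition20):
        ranks = np.arange(1, 21)
        mid = score_from_rank(ranks, partition20, "mid")
        left = score_from_rank(ranks, partition20, "left")
        right = score_from_rank(ranks, partition20, "right")
        assert (np.diff(mid) > 0).all() and (np.diff(left) > 0).all()
        np.testing.assert_allclose(right - left, partition20.width)
        np.testing.assert_allclose(mid - left, partition20.width / 2)

    def test_out_of_range(self, partition20):
        with pytest.raises(ValueError):
            score_from_rank(0, partition20)
        with pytest.raises(ValueError):
            score_from_rank(21, partition20)

    @pytest.mark.parametrize("K", [2, 5, 20])
    def test_decode_label_round_trip(self, K):
        p = IntervalPartition(0.0, 1.0, K)
        for r in range(1, K + 1):
            assert label_of_score(score_from_rank(r, p, "mid"), p) == r


class TestCallPpi:
    @pytest.mark.parametrize("score,theta,expected", [(0.51, 0.5, True), (0.5, 0.5, False)])
    def test_strict(self, score, theta, expected):
        assert call_ppi(score, theta) is expected

    def test_sweep_monotone_positive_count(self, rng):
        scores = rng.uniform(0.01, 0.99, size=500)
        counts = [int(call_ppi(scores, th).sum()) for th in np.arange(0.1, 1.0, 0.1)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCrossEntropy:
    def test_uniform_model_gives_ln2(self, rng):
        c = SubClassifier(index=1, mlp=MLPParams.init(rng, 5, 4, 2))
        c.mlp.W2.data[:] = 0.0
        c.mlp.b2.data[:] = 0.0
        x = rng.normal(size=(10, 5))
        labels = np.where(rng.random(10) > 0.5, 1, -1)
        assert cross_entropy_loss(x, labels, c) == pytest.approx(math.log(2.0))

    def test_confident_correct_model_near_zero(self, rng):
        c = SubClassifier(index=1, mlp=MLPParams.init(rng, 5, 4, 2))
        c.mlp.W2.data[:] = 0.0
        c.mlp.b2.data[:] = [60.0, -60.0]
        x = rng.normal(size=(8, 5))
        assert cross_entropy_loss(x, np.ones(8), c) < 1e-12

    def test_matches_per_item_summation(self, rng):
        c = SubClassifier(index=1, mlp=MLPParams.init(rng, 5, 16, 2))
        x = rng.normal(size=(30, 5))
        labels = np.where(rng.random(30) > 0.4, 1, -1)
        s1, s2 = subclassifier_forward(x, c)
        probs_true = [s1[i] if labels[i] > 0 else s2[i] for i in range(30)]
        assert cross_entropy_loss(x, labels, c) == pytest.approx(
            two_term_cross_entropy(probs_true), rel=1e-10
        )


class TestRegressionHead:
    def test_scalar_output_in_open_range(self, rng):
        head = RegressionHead.init(rng, 6, 8, IntervalPartition(0.0, 1.0, 20))
        out = head.forward(rng.normal(size=6))
        assert isinstance(out, float)
        assert 0.0 < out < 1.0

    def test_deterministic(self, rng):
        head = RegressionHead.init(rng, 6, 8, IntervalPartition(0.0, 1.0, 20))
        x = rng.normal(size=6)
        assert head.forward(x) == head.forward(x.copy())


class TestModelCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        config = RCNNConfig(num_units=1, kernel_width=3, hidden_dim=5, pool_width=2, in_dim=7)
        model = OrdinalModel.init(config, IntervalPartition(0.0, 1.0, 4), hidden=6, seed=2)
        x = rng.normal(size=(3, 5))
        before = model.decisions_from_encoding(x)
        path = tmp_path / "model.npz"
        model.save(path)
        back = OrdinalModel.load(path)
        np.testing.assert_array_equal(before, back.decisions_from_encoding(x))
        assert back.partition == model.partition
        assert len(back.heads) == 3


class TestAssignLabels:
    def test_labels_match_interval_membership(self, partition20, rng):
        scores = rng.uniform(0.01, 0.99, size=100)
        pairs = labeled_pairs(scores, partition20)
        for pair in pairs:
            lo = partition20.width * (pair.label - 1)
            hi = lo + partition20.width
            assert lo <= pair.score < hi or (pair.label == 1 and 0 < pair.score < hi)
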