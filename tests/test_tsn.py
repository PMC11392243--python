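"""Temporal-segment feature extractor: snippet sampling, consensus, the
cross-entropy loss against an independent literal-formula oracle, training
behaviour and the 1024-d feature contract."""

import math

import numpy as np
import pytest

from echoflow.flow import FlowFrameEncoding
from echoflow.tsn import (ConsensusConfig, FEATURE_DIM, TemporalConvNet,
                          extract_features, sample_snippets, segmental_consensus,
                          snippet_scores, train_backbone, tsn_loss)


def _encs(n_pairs, size=32, seed=0):
    rng = np.random.default_rng(seed)
    return [FlowFrameEncoding(x_frame=rng.integers(0, 256, (size, size), dtype=np.uint8),
                              y_frame=rng.integers(0, 256, (size, size), dtype=np.uint8),
                              clip=20.0, t=t)
            for t, n in enumerate(range(n_pairs))]


def _loss_oracle(G, y):
    """Independent literal transcription: L = -sum_i y_i (G_i - log sum_j e^G_j)."""
    lse = math.log(sum(math.exp(g) for g in G))
    return -sum(yi * (gi - lse) for yi, gi in zip(y, G))


class TestSampleSnippets:
    def test_stack_shape_is_10_channels(self):
        snips = sample_snippets(_encs(74, size=224), ConsensusConfig(k=7))
        assert len(snips) == 7
        assert all(s.stack.shape == (10, 224, 224) for s in snips)
        assert [s.segment_index for s in snips] == list(range(7))

    def test_exact_length_forces_zero_offsets(self):
        encs = _encs(35)
        center = sample_snippets(encs, ConsensusConfig(k=7, sampling_mode="center"))
        rand = sample_snippets(encs, ConsensusConfig(k=7, sampling_mode="random"), seed=0)
        for c, r in zip(center, rand):
            assert np.array_equal(c.stack, r.stack)

    def test_too_short_sequence_reports_minimum(self):
        with pytest.raises(ValueError, match="35"):
            sample_snippets(_encs(10), ConsensusConfig(k=7))

    def test_random_mode_deterministic_under_seed(self):
        encs = _encs(74)
        cfg = ConsensusConfig(k=7, sampling_mode="random")
        a = sample_snippets(encs, cfg, seed=42)
        b = sample_snippets(encs, cfg, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.stack, y.stack)

    def test_values_are_zero_centred(self):
        snips = sample_snippets(_encs(35), ConsensusConfig(k=7))
        v = np.concatenate([s.stack.ravel() for s in snips])
        assert v.min() >= -1.0 and v.max() <= 1.0


class TestConsensus:
    def test_average_of_two(self):
        G = segmental_consensus(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(G, [0.5, 0.5])

    def test_permutation_invariant(self, rng):
        scores = rng.normal(size=(7, 2))
        G = segmental_consensus(scores)
        for _ in range(20):
            assert np.allclose(segmental_consensus(rng.permutation(scores)), G)

    def test_idempotent_on_identical_vectors(self):
        s = np.array([0.3, -1.2])
        assert np.allclose(segmental_consensus(np.tile(s, (7, 1))), s)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            segmental_consensus(np.empty((0, 2)))


class TestLoss:
    def test_uniform_logits_give_ln2(self):
        assert tsn_loss(np.zeros(2), np.array([1.0, 0.0])) == pytest.approx(math.log(2))

    def test_large_margin_drives_loss_to_zero(self):
        loss = tsn_loss(np.array([10.0, -10.0]), np.array([1.0, 0.0]))
        assert 0 <= loss < 1e-8
        assert loss == pytest.approx(2.061e-9, rel=1e-2)

    def test_matches_literal_formula_over_1000_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            c = int(rng.integers(2, 6))
            G = rng.normal(0, 3, c)
            y = np.zeros(c)
            y[rng.integers(0, c)] = 1.0
            assert tsn_loss(G, y) == pytest.approx(_loss_oracle(G, y), abs=1e-12)

    def test_equals_minus_log_softmax_probability(self, rng):
        for _ in range(50):
            G = rng.normal(size=3)
            y = np.zeros(3)
            k = rng.integers(0, 3)
            y[k] = 1.0
            p = np.exp(G) / np.exp(G).sum()
            assert tsn_loss(G, y) == pytest.approx(-np.log(p[k]), rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tsn_loss(np.zeros(3), np.zeros(2))


@pytest.fixture(scope="module")
def backbone():
    return TemporalConvNet(n_classes=2, seed=0)


class TestBackbone:
    def test_shared_parameters_give_identical_scores(self, backbone):
        snips = sample_snippets(_encs(35), ConsensusConfig(k=7))
        dup = [snips[0]] * 7
        out = snippet_scores(backbone, dup)
        assert np.allclose(out.scores, out.scores[0])
        assert np.allclose(out.consensus, out.scores[0])

    def test_prediction_recomposes_from_parts(self, backbone):
        """Video prediction == softmax(consensus(per-snippet scores)) exactly."""
        snips = sample_snippets(_encs(35), ConsensusConfig(k=7))
        out = snippet_scores(backbone, snips)
        manual = np.exp(out.consensus) / np.exp(out.consensus).sum()
        assert np.allclose(out.probabilities, manual)
        assert out.probabilities.sum() == pytest.approx(1.0)
        assert np.allclose(out.consensus, out.scores.mean(axis=0))

    def test_k1_consensus_is_that_snippets_scores(self, backbone):
        snips = sample_snippets(_encs(10), ConsensusConfig(k=1))
        out = snippet_scores(backbone, snips)
        assert np.allclose(out.consensus, out.scores[0])

    def test_scores_deterministic(self, backbone):
        snips = sample_snippets(_encs(35), ConsensusConfig(k=7))
        a = snippet_scores(backbone, snips).scores
        b = snippet_scores(backbone, snips).scores
        assert np.array_equal(a, b)

    def test_channel_mismatch_rejected(self, backbone):
        with pytest.raises(ValueError, match="10"):
            backbone.forward(np.zeros((1, 6, 32, 32), np.float32))


class TestTraining:
    def _seqs(self, n=4, seed=0):
        seqs = [_encs(35, seed=seed + i) for i in range(n)]
        labels = ["RWMA", "non-RWMA"] * (n // 2)
        return seqs, labels

    def test_zero_lr_leaves_parameters(self):
        bb = TemporalConvNet(2, seed=1)
        before = [p.value.copy() for p in bb.params()]
        seqs, labels = self._seqs()
        train_backbone(bb, seqs, labels, epochs=1, seed=0, lr=0.0)
        for b, p in zip(before, bb.params()):
            assert np.array_equal(b, p.value)

    def test_loss_falls_and_is_seed_reproducible(self):
        finals = []
        for _ in range(2):
            bb = TemporalConvNet(2, seed=1)
            seqs, labels = self._seqs()
            hist = train_backbone(bb, seqs, labels, epochs=4, seed=3)
            assert hist[-1] < hist[0]
            finals.append(hist[-1])
        assert finals[0] == finals[1]

    def test_single_class_rejected(self):
        bb = TemporalConvNet(2, seed=1)
        seqs, _ = self._seqs()
        with pytest.raises(ValueError, match="class"):
            train_backbone(bb, seqs, ["RWMA"] * 4, epochs=1)


class TestExtractFeatures:
    def test_feature_length_is_1024(self):
        bb = TemporalConvNet(2, seed=0)
        feat = extract_features(bb, _encs(35), view="A2C")
        assert feat.values.shape == (FEATURE_DIM,)
        assert np.all(np.isfinite(feat.values))
        assert feat.view == "A2C"

    def test_deterministic_at_inference(self):
        bb = TemporalConvNet(2, seed=0)
        encs = _encs(40)
        a = extract_features(bb, encs).values
        b = extract_features(bb, encs).values
        assert np.array_equal(a, b)

    def test_distinct_inputs_yield_distinct_features(self):
        bb = TemporalConvNet(2, seed=0)
        size = 32
        zero = [FlowFrameEncoding(np.full((size, size), 128, np.uint8),
                                  np.full((size, size), 128, np.uint8), 20.0, t)
                for t in range(35)]
        a = extract_features(bb, zero).values
        b = extract_features(bb, _encs(35)).values
        assert np.linalg.norm(a - b) > 0
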