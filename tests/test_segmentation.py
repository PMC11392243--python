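"""Segmentation network: architecture contracts, training, masking, metrics."""

import numpy as np
import pytest

from echoflow import nn
from echoflow.phantom import EchoSequence, PhantomConfig, generate_sequence
from echoflow.segmentation import (UNetConfig, apply_masks,
                                   build_segmenter, conv_layers, dice,
                                   evaluate_segmentation, segment_sequence,
                                   train_segmenter)


@pytest.fixture(scope="module")
def tiny_segmenter():
    return build_segmenter(UNetConfig(depth=3, base_channels=4, input_size=32), seed=0)


class TestArchitecture:
    def test_default_config_has_23_convolutional_layers(self):
        seg = build_segmenter()
        assert len(conv_layers(seg)) == 23

    @pytest.mark.parametrize("depth,expected", [(3, 13), (4, 18), (5, 23)])
    def test_conv_count_follows_depth(self, depth, expected):
        seg = build_segmenter(UNetConfig(depth=depth, base_channels=4,
                                         input_size=2 ** (depth - 1) * 4))
        assert len(conv_layers(seg)) == expected

    def test_output_mask_matches_224_input(self):
        seg = build_segmenter(UNetConfig(depth=5, base_channels=4, input_size=224))
        prob = seg.predict_proba(np.zeros((1, 224, 224), dtype=np.float32))
        assert prob.shape == (1, 224, 224)

    def test_class_scores_normalise_to_one(self, tiny_segmenter):
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        logits = tiny_segmenter.net.forward(x)
        probs = nn.softmax(logits, axis=1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_segmenter(UNetConfig(depth=5, input_size=100))


class TestTraining:
    def _data(self, n=6, size=32, seed=0):
        cfg = PhantomConfig(image_size=size, frames_per_cycle=4, n_cycles=1, seed=seed)
        frames, masks = [], []
        for i in range(n // 2):
            cfg2 = PhantomConfig(image_size=size, frames_per_cycle=4, n_cycles=1,
                                 seed=seed + i)
            seq, gt = generate_sequence(cfg2)
            frames.extend(seq.frames[:2])
            masks.extend(gt.wall_masks[:2])
        return np.asarray(frames), np.asarray(masks)

    def test_zero_epochs_returns_unchanged(self, tiny_segmenter):
        before = [p.value.copy() for p in tiny_segmenter.net.params()]
        frames, masks = self._data()
        train_segmenter(tiny_segmenter, frames, masks, epochs=0)
        for b, p in zip(before, tiny_segmenter.net.params()):
            assert np.array_equal(b, p.value)

    def test_loss_decreases_and_seed_reproducible(self):
        frames, masks = self._data()
        final = []
        for _ in range(2):
            seg = build_segmenter(UNetConfig(depth=3, base_channels=4,
                                             input_size=32), seed=3)
            train_segmenter(seg, frames, masks, epochs=3, seed=5)
            assert seg.history[-1] < seg.history[0]
            final.append(seg.history[-1])
        assert final[0] == final[1]

    def test_empty_training_set_rejected(self, tiny_segmenter):
        with pytest.raises(ValueError, match="empty"):
            train_segmenter(tiny_segmenter, np.empty((0, 32, 32)),
                            np.empty((0, 32, 32)), epochs=1)


class TestSegmentSequence:
    def test_one_mask_per_frame_and_masking_identity(self, tiny_segmenter):
        cfg = PhantomConfig(image_size=32, frames_per_cycle=5, n_cycles=1, seed=2)
        seq, _ = generate_sequence(cfg)
        masks, masked = segment_sequence(tiny_segmenter, seq)
        assert len(masks) == 5
        stack = np.stack([m.mask for m in masks])
        assert np.array_equal(masked.frames, seq.frames * stack)
        # idempotence: re-masking with the same masks changes nothing
        again = apply_masks(masked, stack)
        assert np.array_equal(again.frames, masked.frames)

    def test_all_zero_frames_give_all_zero_masked(self, tiny_segmenter):
        seq = EchoSequence(frames=np.zeros((3, 32, 32), np.float32),
                           view="A4C", subject_id="z", label="non-RWMA")
        _, masked = segment_sequence(tiny_segmenter, seq)
        assert np.all(masked.frames == 0)

    def test_shape_mismatch_rejected(self, tiny_segmenter):
        seq = EchoSequence(frames=np.zeros((2, 48, 48), np.float32),
                           view="A4C", subject_id="z", label="non-RWMA")
        with pytest.raises(ValueError, match="input_size"):
            segment_sequence(tiny_segmenter, seq)


class TestEvaluateSegmentation:
    def test_perfect_prediction_scores_100(self):
        m = np.random.default_rng(0).random((3, 8, 8)) > 0.5
        rep = evaluate_segmentation(m, m)
        for v in (rep.sensitivity, rep.precision, rep.f1, rep.accuracy):
            assert v == pytest.approx(100.0)

    def test_complement_prediction_has_zero_sensitivity(self):
        m = np.random.default_rng(1).random((2, 8, 8)) > 0.5
        rep = evaluate_segmentation(~m, m)
        assert rep.sensitivity == 0.0

    def test_matches_bruteforce_pixel_counting(self, rng):
        pred = rng.random((1, 16, 16)) > 0.4
        true = rng.random((1, 16, 16)) > 0.6
        tp = tn = fp = fn = 0
        for p, t in zip(pred.ravel(), true.ravel()):
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
        rep = evaluate_segmentation(pred, true)
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / 256)
        assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert rep.precision == pytest.approx(100 * tp / (tp + fp))
        assert rep.f1 == pytest.approx(100 * 2 * tp / (2 * tp + fp + fn))

    def test_pixel_accuracy_identity(self, rng):
        pred = rng.random((2, 8, 8)) > 0.5
        true = rng.random((2, 8, 8)) > 0.5
        rep = evaluate_segmentation(pred, true)
        assert rep.accuracy == pytest.approx(100 * np.mean(pred == true))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((1, 4, 4)), np.zeros((2, 4, 4)))


def test_dice_bounds():
    a = np.ones((2, 4, 4), bool)
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
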