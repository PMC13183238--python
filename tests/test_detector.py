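"""Detector mechanics: decoding, assignment, NMS, loss behavior."""

import numpy as np
import pytest

from ktyolo.detector import Detector, nms
from ktyolo.losses import SlideLossParams
from ktyolo.netgraph import ModelConfig, build_detector
from ktyolo.nn import SGD

TINY = ModelConfig(num_classes=4, widths=(4, 8, 8, 16, 16), depths=(1, 1, 1, 1), fusion="ktf")


@pytest.fixture(scope="module")
def tiny_detector():
    g = build_detector(TINY)
    g.input_size = (64, 64)
    return Detector(g, seed=0)


class TestNms:
    def test_suppresses_heavy_overlap_keeps_distinct(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]], float)
        scores = np.array([0.9, 0.8, 0.7])
        assert nms(boxes, scores, 0.5) == [0, 2]

    def test_keeps_all_below_threshold(self):
        boxes = np.array([[0, 0, 10, 10], [20, 0, 30, 10]], float)
        assert nms(boxes, np.array([0.5, 0.9]), 0.5) == [1, 0]


class TestDecode:
    def test_decode_inverts_assignment(self, tiny_detector):
        """Logits concentrated on the target bins decode back to the box."""
        det = tiny_detector
        gt = np.array([[10.0, 14.0, 34.0, 38.0]])  # 24x24 box -> level 0
        targets = det._assign(gt, np.array([1]), [(8, 8), (4, 4), (2, 2)])
        assert len(targets[0]) == 1 and not targets[1] and not targets[2]
        (i, j), (ltrb, cls) = next(iter(targets[0].items()))
        assert cls == 1
        # softmax(log p) = p, so log-probability logits realize the target
        # two-bin distribution exactly
        logits = np.full((1, 4 * det.reg_max, 8, 8), -40.0, dtype=np.float32)
        for side in range(4):
            lo = int(np.floor(ltrb[side]))
            hi = min(lo + 1, det.reg_max - 1)
            w_hi = float(ltrb[side] - lo)
            logits[0, side * det.reg_max + lo, i, j] = np.log(max(1 - w_hi, 1e-12))
            logits[0, side * det.reg_max + hi, i, j] = np.log(max(w_hi, 1e-12))
        boxes, _, _ = det.decode_level(logits, stride=8)
        decoded = boxes[0, i, j]
        assert decoded == pytest.approx(gt[0], abs=1.0)

    def test_large_objects_go_to_coarser_levels(self, tiny_detector):
        det = tiny_detector
        gts = np.array([[0.0, 0.0, 150.0, 150.0], [0.0, 0.0, 300.0, 300.0]])
        targets = det._assign(gts, np.array([0, 0]), [(80, 80), (40, 40), (20, 20)])
        assert len(targets[1]) == 1 and len(targets[2]) == 1

    def test_collision_keeps_smaller_object(self, tiny_detector):
        det = tiny_detector
        gts = np.array([[0.0, 0.0, 60.0, 60.0], [24.0, 24.0, 40.0, 40.0]])
        targets = det._assign(gts, np.array([0, 1]), [(8, 8), (4, 4), (2, 2)])
        cells = {lvl: list(t.values()) for lvl, t in enumerate(targets) if t}
        flat = [v for vs in cells.values() for v in vs]
        # both may land on distinct cells; if they collide, class 1 (smaller) wins
        classes = [cls for _, cls in flat]
        assert 1 in classes


class TestLoss:
    def test_loss_and_grads_are_finite_and_shaped(self, tiny_detector):
        det = tiny_detector
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(2, 3, 64, 64)).astype(np.float32)
        outs = det.forward(x, train=True)
        gts = [
            (np.array([[5.0, 5.0, 25.0, 30.0]]), np.array([0])),
            (np.zeros((0, 4)), np.zeros(0, int)),
        ]
        loss, grads, ious = det.compute_loss_and_grads(outs, gts)
        assert np.isfinite(loss.total) and loss.n_pos == 1
        for (gb, gc), (bl, cl) in zip(grads, outs):
            assert gb.shape == bl.shape and gc.shape == cl.shape
            assert np.all(np.isfinite(gb)) and np.all(np.isfinite(gc))

    def test_slide_weighting_changes_only_positive_cls_grads(self, tiny_detector):
        det = tiny_detector
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=(1, 3, 64, 64)).astype(np.float32)
        outs = det.forward(x, train=True)
        gts = [(np.array([[8.0, 8.0, 30.0, 30.0]]), np.array([2]))]
        _, g_bce, ious = det.compute_loss_and_grads(outs, gts, cls_loss="bce")
        # place the positive's IoU inside the transition interval, where the
        # slide weight is e^(1-mu) > 1 rather than 1
        mu = float(np.clip(ious[0] + 0.05, 0.0, 1.0))
        _, g_slide, _ = det.compute_loss_and_grads(
            outs, gts, cls_loss="slide", slide_params=SlideLossParams(mu=mu)
        )
        assert not np.allclose(g_bce[0][1], g_slide[0][1])
        # box gradients identical: slide reweights classification only
        for (gb1, _), (gb2, _) in zip(g_bce, g_slide):
            assert np.allclose(gb1, gb2)

    def test_training_steps_reduce_loss_on_fixed_batch(self):
        g = build_detector(TINY)
        g.input_size = (64, 64)
        det = Detector(g, seed=3)
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(2, 3, 64, 64)).astype(np.float32)
        gts = [
            (np.array([[5.0, 5.0, 25.0, 30.0]]), np.array([0])),
            (np.array([[30.0, 30.0, 55.0, 50.0]]), np.array([2])),
        ]
        opt = SGD(det.parameters(), lr=0.01)
        first = det.train_step(x, gts, opt).total
        for _ in range(14):
            last = det.train_step(x, gts, opt).total
        assert last < first

    def test_identical_seeds_give_identical_outputs(self):
        rng_in = np.random.default_rng(7)
        x = rng_in.uniform(0, 1, size=(1, 3, 64, 64)).astype(np.float32)
        outs = []
        for _ in range(2):
            g = build_detector(TINY)
            g.input_size = (64, 64)
            det = Detector(g, seed=11)
            outs.append(det.forward(x, train=False))
        for (b1, c1), (b2, c2) in zip(*outs):
            assert np.array_equal(b1, b2) and np.array_equal(c1, c2)

    def test_predict_returns_valid_records(self, tiny_detector):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, size=(1, 3, 64, 64)).astype(np.float32)
        preds = tiny_detector.predict(x, ["imA"], score_thresh=0.001)
        for r in preds[0]:
            assert r.image_id == "imA"
            assert 0 <= r.class_id < 4
            x1, y1, x2, y2 = r.box
            assert x2 > x1 and y2 > y1
            assert 0.0 <= r.score <= 1.0
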