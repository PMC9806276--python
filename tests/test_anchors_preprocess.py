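import itertools

import numpy as np
import pytest

from spotspray.detector import kmeans_anchors, letterbox, mosaic_augment
from spotspray.detector.anchors import iou_wh


class TestKMeansAnchors:
    def test_identical_boxes_collapse_to_one_size(self):
        boxes = np.tile([30.0, 40.0], (20, 1))
        anchors = kmeans_anchors(boxes, k=3, seed=0)
        assert np.allclose(anchors, [30, 40])

    def test_k_distinct_boxes_returned_exactly(self):
        boxes = np.array([[10, 10], [30, 15], [60, 80]], float)
        anchors = kmeans_anchors(boxes, k=3, seed=1)
        assert np.allclose(np.sort(anchors, axis=0), np.sort(boxes, axis=0))

    def test_two_separated_clusters_recover_means(self):
        """Against exhaustive assignment: with k=2 the best partition of two
        tight, well-separated clusters is the clusters themselves."""
        rng = np.random.default_rng(2)
        small = rng.uniform(9, 11, (8, 2))
        large = rng.uniform(95, 105, (8, 2))
        boxes = np.vstack([small, large])
        anchors = kmeans_anchors(boxes, k=2, seed=3)

        best_cost, best_means = np.inf, None
        for mask_bits in itertools.product([0, 1], repeat=len(boxes)):
            mask = np.array(mask_bits, bool)
            if not mask.any() or mask.all():
                continue
            means = np.stack([boxes[mask].mean(0), boxes[~mask].mean(0)])
            cost = (1 - iou_wh(boxes, means).max(axis=1)).sum()
            if cost < best_cost:
                best_cost, best_means = cost, means
        order = np.argsort(best_means[:, 0] * best_means[:, 1])
        assert np.allclose(anchors, best_means[order], rtol=1e-6)

    def test_fewer_boxes_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            kmeans_anchors(np.array([[5.0, 5.0]]), k=9)

    def test_sorted_by_area_and_deterministic(self):
        rng = np.random.default_rng(4)
        boxes = rng.uniform(5, 200, (60, 2))
        a1 = kmeans_anchors(boxes, k=9, seed=7)
        a2 = kmeans_anchors(boxes, k=9, seed=7)
        assert np.array_equal(a1, a2)
        areas = a1[:, 0] * a1[:, 1]
        assert np.all(np.diff(areas) >= 0)


class TestLetterbox:
    def test_hd_frame_pads_140_top_and_bottom(self):
        image = np.zeros((1080, 1920, 3), np.uint8)
        padded, tf = letterbox(image, 640)
        assert padded.shape == (640, 640, 3)
        assert tf.scale == pytest.approx(1 / 3)
        assert tf.pad_y == 140 and tf.pad_x == 0
        assert np.all(padded[:140] == 114) and np.all(padded[-140:] == 114)
        assert np.all(padded[140:500] == 0)

    def test_square_input_unchanged(self):
        image = np.full((640, 640), 7, np.uint8)
        padded, tf = letterbox(image, 640)
        assert np.array_equal(padded, image)
        assert (tf.scale, tf.pad_x, tf.pad_y) == (1.0, 0, 0)

    def test_upscaling_small_square(self):
        image = np.full((320, 320), 3, np.uint8)
        padded, tf = letterbox(image, 640)
        assert tf.scale == 2.0 and tf.pad_x == 0 and tf.pad_y == 0
        assert padded.shape == (640, 640)

    def test_box_remap_round_trips(self):
        _, tf = letterbox(np.zeros((1080, 1920), np.uint8), 640)
        boxes = np.array([[100, 200, 700, 900], [0, 0, 1920, 1080]], float)
        assert np.allclose(tf.invert_boxes(tf.apply_boxes(boxes)), boxes)


class TestMosaic:
    @staticmethod
    def _sample(rng, size=200, n_boxes=3):
        img = rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
        xy1 = rng.uniform(0, size - 20, (n_boxes, 2))
        wh = rng.uniform(5, 40, (n_boxes, 2))
        boxes = np.hstack([xy1, np.minimum(xy1 + wh, size)])
        return img, boxes

    def test_all_boxes_inside_canvas(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            samples = [self._sample(rng) for _ in range(4)]
            canvas, boxes = mosaic_augment(samples, 640, rng=rng)
            assert canvas.shape[:2] == (640, 640)
            if len(boxes):
                assert boxes.min() >= 0 and boxes.max() <= 640
                assert np.all(boxes[:, 2] - boxes[:, 0] >= 2)
                assert np.all(boxes[:, 3] - boxes[:, 1] >= 2)

    def test_fixed_center_with_identical_inputs_gives_congruent_quadrants(self):
        rng = np.random.default_rng(1)
        sample = self._sample(rng, size=160)
        canvas, _ = mosaic_augment([sample] * 4, 640, center=(320, 320))
        assert np.array_equal(canvas[:320, :320], canvas[:320, 320:])
        assert np.array_equal(canvas[:320, :320], canvas[320:, :320])
        assert np.array_equal(canvas[:320, :320], canvas[320:, 320:])

    def test_box_remap_equals_per_box_affine(self):
        rng = np.random.default_rng(2)
        img = np.zeros((100, 100, 3), np.uint8)
        boxes = np.array([[10, 20, 30, 60]], float)
        cx, cy = 256, 384
        canvas, out = mosaic_augment([(img, boxes)] * 4, 640, center=(cx, cy))
        # quadrant 0 occupies [0, cx) x [0, cy): scale (cx/100, cy/100)
        expected_q0 = np.array([10 * cx / 100, 20 * cy / 100,
                                30 * cx / 100, 60 * cy / 100])
        assert np.allclose(out[0], expected_q0)

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError):
            mosaic_augment([], 640)
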