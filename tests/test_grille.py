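import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotspray import (GrilleConfig, InvalidConfigurationError, PredictionBox,
                       Rect, build_grille, decide_frame, decision_stream,
                       intersection_area)


def rasterized_overlap(box: PredictionBox, cell: Rect) -> int:
    """Brute-force oracle: count integer pixels inside both rectangles."""
    count = 0
    for x in range(int(min(box.x1, cell.x1)), int(max(box.x2, cell.x2)) + 1):
        for y in range(int(min(box.y1, cell.y1)), int(max(box.y2, cell.y2)) + 1):
            if box.x1 <= x < box.x2 and box.y1 <= y < box.y2 \
                    and cell.x1 <= x < cell.x2 and cell.y1 <= y < cell.y2:
                count += 1
    return count


class TestBuildGrille:
    def test_default_tiling_11_cells_1920(self):
        cells = build_grille(GrilleConfig())
        widths = [c.x2 - c.x1 for c in cells]
        assert sorted(widths, reverse=True) == [175] * 6 + [174] * 5
        assert widths == sorted(widths, reverse=True)  # remainder left-to-right
        assert sum(widths) == 1920

    def test_single_cell_spans_image(self):
        (cell,) = build_grille(GrilleConfig(n_cells=1))
        assert (cell.x1, cell.x2) == (0, 1920)

    @pytest.mark.parametrize("n_cells,width", [(7, 100), (11, 1920), (13, 640)])
    def test_cells_disjoint_and_cover_row(self, n_cells, width):
        cfg = GrilleConfig(n_cells=n_cells, image_width_px=width)
        cells = build_grille(cfg)
        edges = [c.x1 for c in cells] + [cells[-1].x2]
        assert edges == sorted(edges)
        assert edges[0] == 0 and edges[-1] == width
        assert all(c.y2 - c.y1 == cfg.row_height_px for c in cells)

    def test_more_cells_than_pixels_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            GrilleConfig(n_cells=30, image_width_px=20)


class TestIntersectionArea:
    def test_disjoint_and_contained(self):
        cell = Rect(100, 100, 200, 160)
        assert intersection_area(PredictionBox(0, 0, 50, 50), cell) == 0
        assert intersection_area(PredictionBox(0, 0, 500, 500), cell) == cell.area

    def test_partial_overlap_matches_hand_value(self):
        area = intersection_area(PredictionBox(100, 500, 250, 600),
                                 Rect(174, 480, 349, 540))
        assert area == (250 - 174) * (540 - 500) == 3040

    def test_equals_pixel_rasterization_on_random_pairs(self):
        """Analytic overlap equals brute-force pixel counting exactly."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x1, y1 = rng.integers(0, 80, 2)
            box = PredictionBox(x1, y1, x1 + rng.integers(1, 60),
                                y1 + rng.integers(1, 60))
            cx1, cy1 = rng.integers(0, 80, 2)
            cell = Rect(cx1, cy1, cx1 + rng.integers(1, 60), cy1 + rng.integers(1, 60))
            assert intersection_area(box, cell) == rasterized_overlap(box, cell)


class TestDecideFrame:
    def test_no_boxes_all_closed(self):
        assert decide_frame([], GrilleConfig()).bits == (0,) * 11

    def test_box_spanning_two_cells(self):
        cfg = GrilleConfig()
        # cells 3 and 4 cover x in [525, 875); default row starts at 1020
        box = PredictionBox(600, 1000, 800, 1080)
        assert decide_frame([box], cfg).bits == (0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0)

    def test_threshold_is_strict(self):
        cfg = GrilleConfig(n_cells=2, image_width_px=200, image_height_px=100,
                           row_height_px=50, area_threshold_px2=100 * 50)
        exactly_cell = PredictionBox(0, 50, 100, 100)
        assert decide_frame([exactly_cell], cfg).bits == (0, 0)
        just_below = GrilleConfig(n_cells=2, image_width_px=200, image_height_px=100,
                                  row_height_px=50, area_threshold_px2=100 * 50 - 1)
        assert decide_frame([exactly_cell], just_below).bits == (1, 0)

    def test_other_class_ignored(self):
        cfg = GrilleConfig()
        box = PredictionBox(0, 1020, 1920, 1080, class_id=3)
        assert decide_frame([box], cfg).bits == (0,) * 11

    def test_frame_decision_is_or_of_singletons(self):
        rng = np.random.default_rng(3)
        cfg = GrilleConfig(area_threshold_px2=500)
        boxes = []
        for _ in range(8):
            x1, x2 = np.sort(rng.uniform(0, 1920, 2) + [0, 1])
            y1, y2 = np.sort(rng.uniform(900, 1080, 2) + [0, 1])
            boxes.append(PredictionBox(x1, y1, x2, y2))
        combined = decide_frame(boxes, cfg).bits
        ored = tuple(int(any(decide_frame([b], cfg).bits[i] for b in boxes))
                     for i in range(cfg.n_cells))
        assert combined == ored

    @given(x1=st.floats(0, 1800), w=st.floats(5, 120), grow=st.floats(0, 50),
           thr=st.floats(0, 2000), raise_thr=st.floats(0, 2000))
    @settings(max_examples=150, deadline=None)
    def test_monotone_under_dilation_and_threshold(self, x1, w, grow, thr, raise_thr):
        """Enlarging a box never clears a bit; raising the threshold never sets one."""
        cfg = GrilleConfig(area_threshold_px2=thr)
        box = PredictionBox(x1, 990, x1 + w, 1060)
        bigger = PredictionBox(max(x1 - grow, 0), 990 - grow,
                               min(x1 + w + grow, 1920), 1060 + grow)
        base = decide_frame([box], cfg).bits
        dilated = decide_frame([bigger], cfg).bits
        stricter = decide_frame([box], GrilleConfig(area_threshold_px2=thr + raise_thr)).bits
        assert all(d >= b for d, b in zip(dilated, base))
        assert all(s <= b for s, b in zip(stricter, base))


class TestDecisionStream:
    def test_stateless_momentary_behaviour(self):
        cfg = GrilleConfig()
        box = PredictionBox(100, 1000, 300, 1080)
        stream = decision_stream([[box], [box], []], cfg)
        assert stream[0].bits == stream[1].bits
        assert any(stream[0].bits)
        assert stream[2].bits == (0,) * 11

    def test_moving_box_sets_bits_only_while_overlapping(self):
        """A box scrolling downward trips the grille exactly in the frames
        where its overlap with the row exceeds the threshold."""
        cfg = GrilleConfig(area_threshold_px2=0.0)
        frames = []
        for step in range(12):
            y1 = 850 + step * 30  # drifts into and past the row at y >= 1020
            y2 = min(y1 + 80, 1080)
            frames.append([PredictionBox(500, y1, 700, y2)] if y2 > y1 else [])
        stream = decision_stream(frames, cfg)
        for boxes, vector in zip(frames, stream):
            expect = int(bool(boxes) and boxes[0].y2 > 1020 and boxes[0].y1 < 1080)
            assert any(vector.bits) == bool(expect)
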