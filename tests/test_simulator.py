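from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from spotspray import (CameraSetup, GrilleConfig, SimParams, coverage_map,
                       frames_in_band, generate_scene, ground_scale,
                       render_frame, simulate_pass, speed_sweep)
from spotspray.protocol import ValveTimeline

IDEAL = SimParams(speed_kmh=2.0, p_detect_frame=1.0, sigma_loc_mm=0.0,
                  sigma_vib_mm_per_kmh=0.0, spray_margin_m=0.0, seed=1)


class TestGenerateScene:
    def test_zero_density_empty(self):
        assert generate_scene(0.0, seed=1).n_weeds == 0

    def test_same_seed_identical(self):
        a, b = generate_scene(seed=9), generate_scene(seed=9)
        assert np.array_equal(a.weeds, b.weeds)

    def test_count_follows_poisson_law(self):
        """Mean count over 200 seeds lies in the Poisson 99% interval for
        density * area (1/m^2 over 20x3 m -> mean 60)."""
        counts = [generate_scene(1.0, (20, 3), seed=s).n_weeds for s in range(200)]
        lo = stats.poisson.ppf(0.005, 60 * 200)
        hi = stats.poisson.ppf(0.995, 60 * 200)
        assert lo <= sum(counts) <= hi

    def test_weeds_inside_area_with_positive_radii(self):
        scene = generate_scene(3.0, (10, 2), seed=4)
        assert np.all(scene.weeds[:, 0] >= 0) and np.all(scene.weeds[:, 0] <= 10)
        assert np.all(scene.weeds[:, 1] >= 0) and np.all(scene.weeds[:, 1] <= 2)
        assert np.all(scene.weeds[:, 2] > 0)


class TestRenderFrame:
    def test_empty_scene_background_only(self, reference_setup, reference_scale):
        scene = generate_scene(0.0, seed=0)
        image, boxes = render_frame(scene, 1.0, reference_setup, reference_scale)
        assert image.shape == (1080, 1920, 3)
        assert len(boxes) == 0

    def test_single_weed_projects_to_expected_box(self, reference_setup,
                                                  reference_scale):
        from spotspray.simulator import FieldScene

        px_m = reference_scale.mm_per_px / 1000
        # centre of camera 0 footprint: half a frame ahead, mid-span
        wx = 2.0 + 540 * px_m
        wy = (3.0 - 3.3) / 2 + 1.65 / 2
        r = 0.05
        scene = FieldScene(weeds=np.array([[wx, wy, r]]))
        _, boxes = render_frame(scene, 2.0, reference_setup, reference_scale)
        assert len(boxes) == 1
        x1, y1, x2, y2 = boxes[0]
        assert (x1 + x2) / 2 == pytest.approx(960, abs=1.5)
        assert (y1 + y2) / 2 == pytest.approx(540, abs=1.5)
        assert x2 - x1 == pytest.approx(2 * r / px_m, rel=0.02)

    def test_boxes_always_inside_image(self, reference_setup, reference_scale):
        scene = generate_scene(2.0, seed=3)
        for k in range(20):
            _, boxes = render_frame(scene, k, reference_setup, reference_scale,
                                    seed=k, style=["plain", "shadow", "wet",
                                                   "overexposed"][k % 4])
            if len(boxes):
                assert boxes.min() >= 0
                assert boxes[:, [0, 2]].max() <= 1920
                assert boxes[:, [1, 3]].max() <= 1080


class TestSimulatePass:
    def test_ideal_parameters_hit_everything(self, reference_setup,
                                             reference_grille):
        scene = generate_scene(1.5, seed=11)
        res = simulate_pass(scene, IDEAL, reference_grille, reference_setup)
        assert res.rates.u == res.rates.w_rel == res.rates.w_abs == 1.0

    def test_zero_detection_probability(self, reference_setup, reference_grille):
        scene = generate_scene(1.5, seed=11)
        res = simulate_pass(scene, replace(IDEAL, p_detect_frame=0.0),
                            reference_grille, reference_setup)
        assert res.counts.n_identified == 0 and res.counts.n_hit == 0
        assert res.rates.degenerate

    def test_product_identity_on_simulated_counts(self, reference_setup,
                                                  reference_grille):
        scene = generate_scene(1.5, seed=21)
        res = simulate_pass(scene, SimParams(speed_kmh=3.0, seed=2),
                            reference_grille, reference_setup)
        assert res.rates.u * res.rates.w_rel == pytest.approx(res.rates.w_abs,
                                                              rel=1e-12)

    def test_seed_determinism(self, reference_setup, reference_grille):
        scene = generate_scene(1.5, seed=21)
        params = SimParams(speed_kmh=3.0, seed=13)
        a = simulate_pass(scene, params, reference_grille, reference_setup)
        b = simulate_pass(scene, params, reference_grille, reference_setup)
        assert a.counts == b.counts
        assert [e.detected_frames for e in a.events] == \
               [e.detected_frames for e in b.events]

    def test_detection_probability_recovered_from_identifications(
            self, reference_setup, reference_grille):
        """Empirical u must match the per-weed pass probability
        1 - (1-p)^m_i (m_i = frames in band) within a 95% CI."""
        scene = generate_scene(2.0, (90.0, 3.0), seed=31)
        assert scene.n_weeds >= 500
        params = SimParams(speed_kmh=3.0, p_detect_frame=0.35,
                           sigma_loc_mm=0.0, sigma_vib_mm_per_kmh=0.0, seed=17)
        scale = ground_scale(reference_setup)
        m = frames_in_band(scene, params, reference_setup, scale, reference_grille)
        p_pass = 1.0 - (1.0 - params.p_detect_frame) ** m
        res = simulate_pass(scene, params, reference_grille, reference_setup)
        expected = p_pass.sum()
        sd = np.sqrt((p_pass * (1 - p_pass)).sum())
        assert abs(res.counts.n_identified - expected) <= 1.96 * sd

    def test_grille_constraint_warning(self, reference_setup):
        narrow = GrilleConfig(row_height_px=5)
        scene = generate_scene(0.5, seed=2)
        res = simulate_pass(scene, SimParams(speed_kmh=4.0, seed=3), narrow,
                            reference_setup)
        assert res.warnings


class TestCoverageMap:
    def test_strip_length_is_speed_times_duration_plus_margin(self):
        params = SimParams(speed_kmh=3.6, spray_margin_m=0.05, seed=0)  # 1 m/s
        timeline = ValveTimeline([[(2.0, 2.5)]])
        (strip,), = coverage_map(timeline, params)
        assert strip[1] - strip[0] == pytest.approx(0.5 * 1.0 + 0.05)

    def test_disjoint_intervals_disjoint_strips(self):
        params = SimParams(speed_kmh=3.6, spray_margin_m=0.01, seed=0)
        timeline = ValveTimeline([[(0.0, 0.1), (5.0, 5.1)]])
        strips, = coverage_map(timeline, params)
        assert len(strips) == 2

    def test_merged_union_matches_interval_union_oracle(self):
        rng = np.random.default_rng(12)
        starts = np.sort(rng.uniform(0, 30, 25))
        intervals = [(s, s + rng.uniform(0.05, 2.0)) for s in starts]
        params = SimParams(speed_kmh=3.6, spray_margin_m=0.0, seed=0)
        strips, = coverage_map(ValveTimeline([intervals]), params)
        # 1-D union oracle on a fine grid
        xs = np.linspace(-1, 40, 200_001)
        covered = np.zeros_like(xs, bool)
        for a, b in intervals:  # speed 1 m/s: ground == time
            covered |= (xs >= a) & (xs < b)
        oracle = covered.mean() * 41.0
        total = sum(b - a for a, b in strips)
        assert total == pytest.approx(oracle, abs=2e-3)
        assert all(b0 < a1 for (_, b0), (a1, _) in zip(strips, strips[1:]))


class TestSpeedSweep:
    def test_ideal_rates_flat_at_100(self, reference_setup, reference_grille):
        scene = generate_scene(1.0, seed=41)
        table = speed_sweep(scene, [2.0, 3.0, 4.0], IDEAL, reference_grille,
                            reference_setup, n_seeds=2)
        assert len(table) == 3
        assert np.allclose(table["absolute_hit_rate_pct"], 100.0)

    def test_hit_rate_degrades_with_speed_under_vibration(self, reference_setup,
                                                          reference_grille):
        """With speed-coupled vibration, mean absolute hit rate over paired
        seeds is non-increasing from 2 to 4 km/h."""
        scene = generate_scene(1.5, seed=51)
        params = SimParams(seed=7)  # defaults: sigma_vib = 8 mm/(km/h)
        table = speed_sweep(scene, [2.0, 3.0, 4.0], params, reference_grille,
                            reference_setup, n_seeds=12)
        w_abs = table["absolute_hit_rate_pct"].to_numpy()
        assert np.all(np.diff(w_abs) <= 0)

    def test_requires_at_least_two_speeds(self, reference_setup, reference_grille):
        with pytest.raises(ValueError):
            speed_sweep(generate_scene(0.5, seed=1), [2.0], IDEAL,
                        reference_grille, reference_setup)
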