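"""Synthetic weed fields and an in-silico target-spraying pass.

The simulator emulates the field-trial protocol: a boom sprayer drives a
rectangular strip at constant speed while downward cameras image the
ground, detections feed the grille decision algorithm, valve commands are
rate-limited, and sprayed ground strips are compared with weed positions
to produce the (u, w', w) accounting of a trial.

Geometry conventions: ground coordinates in metres with x along the travel
direction (0 at the strip start) and y lateral (0 at the left strip edge);
the boom is centred on the strip.  Per video frame the nozzle line sits at
``x = v * t`` and the grille row of each camera's image maps to the ground
band ``[x + offset, x + offset + row_height_px * scale)`` — the grille row
is the spray impact zone, so a valve opened in a frame wets exactly the
ground passing under its nozzle during that frame (plus the base-opening
extension and the longitudinal redundancy margin).

Speed-dependent degradation is an explicit, configurable emulation of the
mechanical story: nozzle/boom vibration with standard deviation
proportional to speed displaces sprayed strips, and faster travel leaves
fewer frames in which each weed can be detected.  The defaults reproduce
the qualitative decrease of hit rates with speed, with no claim of
matching any particular field trial numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import (CameraSetup, GroundScale, MotionProfile,
                          advance_per_frame, check_grille_constraint,
                          ground_scale)
from .grille import DecisionVector, GrilleConfig, PredictionBox, decide_frame
from .protocol import ValveTimeline, apply_rate_limit, decode_frame, encode_frame
from .spray_metrics import TrialCounts, TrialRates, rates_from_counts
from .seeding import derive_seed


@dataclass(frozen=True)
class FieldScene:
    """A rectangular trial strip with weed positions and canopy radii."""

    length_m: float = 20.0
    width_m: float = 3.0
    weeds: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # x, y, radius [m]

    def __post_init__(self) -> None:
        w = np.asarray(self.weeds, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "weeds", w)
        if len(w):
            if np.any(w[:, 2] <= 0):
                raise ValueError("canopy radii must be positive")
            if (np.any(w[:, 0] < 0) or np.any(w[:, 0] > self.length_m)
                    or np.any(w[:, 1] < 0) or np.any(w[:, 1] > self.width_m)):
                raise ValueError("weeds must lie within the scene area")

    @property
    def n_weeds(self) -> int:
        return len(self.weeds)


@dataclass(frozen=True)
class SimParams:
    """Sprayer-pass parameters.

    ``sigma_vib_mm_per_kmh`` scales nozzle vibration with speed
    (sigma_vib = sigma0 * speed); ``detect_speed_penalty_per_kmh``
    optionally degrades the per-frame detection probability with speed.
    """

    speed_kmh: float = 2.0
    fps: float = 26.73
    p_detect_frame: float = 0.5
    sigma_loc_mm: float = 5.0
    sigma_vib_mm_per_kmh: float = 8.0
    valve_latency_ms: float = 0.0
    nozzle_spacing_m: float = 0.15
    spray_margin_m: float = 0.02
    min_open_s: float = 0.1
    max_valve_freq_hz: float = 10.0
    detect_speed_penalty_per_kmh: float = 0.0
    row_offset_m: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect_frame <= 1.0:
            raise ValueError("p_detect_frame must be in [0, 1]")
        if self.sigma_loc_mm < 0 or self.sigma_vib_mm_per_kmh < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def sigma_vib_mm(self) -> float:
        return self.sigma_vib_mm_per_kmh * self.speed_kmh

    @property
    def p_detect_effective(self) -> float:
        p = self.p_detect_frame * (1.0 - self.detect_speed_penalty_per_kmh
                                   * self.speed_kmh)
        return float(np.clip(p, 0.0, 1.0))


@dataclass
class WeedEvent:
    """Per-weed log: frames it was detected in, and the outcome flags."""

    index: int
    x_m: float
    y_m: float
    radius_m: float
    lane: int
    detected_frames: list[int]
    identified: bool
    hit: bool


@dataclass
class SimResult:
    counts: TrialCounts
    rates: TrialRates
    events: list[WeedEvent]
    timeline: ValveTimeline
    warnings: list[str] = field(default_factory=list)


def generate_scene(density_per_m2: float = 1.5, area: tuple[float, float] = (20.0, 3.0),
                   radius_mean_m: float = 0.03, radius_sigma_log: float = 0.3,
                   seed: int = 0) -> FieldScene:
    """Homogeneous spatial Poisson weed field with log-normal canopy radii.

    Radii are clipped to [0.005, 0.2] m (seedling to large rosette).
    """
    if density_per_m2 < 0:
        raise ValueError("density must be >= 0")
    length, width = area
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_per_m2 * length * width)
    x = rng.uniform(0, length, n)
    y = rng.uniform(0, width, n)
    r = np.clip(rng.lognormal(math.log(radius_mean_m), radius_sigma_log, n),
                0.005, 0.2)
    return FieldScene(length_m=length, width_m=width,
                      weeds=np.stack([x, y, r], axis=1) if n else np.zeros((0, 3)))


def render_frame(scene: FieldScene, vehicle_x_m: float, setup: CameraSetup,
                 scale: GroundScale, camera_index: int = 0, seed: int = 0,
                 style: str = "plain") -> tuple[np.ndarray, np.ndarray]:
    """Render one camera frame as an HWC uint8 image plus ground-truth boxes.

    Soil-textured background with weeds as irregular green blobs at their
    projected pixel positions.  ``style`` emulates adverse capture
    conditions: "plain", "shadow", "wet", "overexposed".  Boxes are xyxy
    pixels, clipped to the image, one per visible weed.
    """
    rng = np.random.default_rng(seed)
    H, W = setup.image_height_px, setup.image_width_px
    px_m = scale.mm_per_px / 1000.0
    base = np.array([120, 92, 70], dtype=float)  # dry soil RGB
    if style == "wet":
        base = base * 0.55
    image = base + rng.normal(0, 8, (H, W, 3))
    if style == "shadow":
        cx, cy = rng.uniform(0.2, 0.8, 2)
        yy, xx = np.mgrid[0:H, 0:W]
        mask = ((xx / W - cx) ** 2 + (yy / H - cy) ** 2) < 0.08
        image[mask] *= 0.5
    boom_y0 = (scene.width_m - setup.boom_width_m) / 2
    cam_y0 = boom_y0 + camera_index * setup.camera_span_m
    view_len = H * px_m
    boxes = []
    yy, xx = np.mgrid[0:H, 0:W]
    for wx, wy, r in scene.weeds:
        # image bottom row = ground x at vehicle position; rows look ahead
        col = (wy - cam_y0) / px_m
        row = H - (wx - vehicle_x_m) / px_m
        r_px = r / px_m
        if not (-r_px < col < W + r_px and -r_px < row < H + r_px):
            continue
        blob = np.zeros((H, W), dtype=bool)
        for _ in range(4):  # irregular canopy: union of offset ellipses
            dx, dy = rng.uniform(-0.4, 0.4, 2) * r_px
            ax_, ay_ = rng.uniform(0.6, 1.0, 2) * r_px
            blob |= (((xx - col - dx) / max(ax_, 1e-6)) ** 2
                     + ((yy - row - dy) / max(ay_, 1e-6)) ** 2) < 1.0
        green = np.array([70, 140, 60], dtype=float) + rng.normal(0, 10, 3)
        image[blob] = green + rng.normal(0, 6, (int(blob.sum()), 3))
        x1, y1 = max(col - r_px, 0), max(row - r_px, 0)
        x2, y2 = min(col + r_px, W), min(row + r_px, H)
        if x2 - x1 >= 1 and y2 - y1 >= 1:
            boxes.append([x1, y1, x2, y2])
    if style == "overexposed":
        image = image * 1.8 + 40
    return (np.clip(image, 0, 255).astype(np.uint8),
            np.array(boxes, dtype=float).reshape(-1, 4))


def frames_in_band(scene: FieldScene, params: SimParams, setup: CameraSetup,
                   scale: GroundScale, grille: GrilleConfig) -> np.ndarray:
    """Number of frames in which each weed's box overlaps the grille band."""
    v = params.speed_kmh / 3.6
    d = (v / params.fps)  # advance per frame [m]
    band_m = grille.row_height_px * scale.mm_per_px / 1000.0
    n_frames = _n_frames(scene, params, band_m)
    wx, r = scene.weeds[:, 0], scene.weeds[:, 2]
    # frame k overlaps iff  wx - r - band < v*k*dt + offset < wx + r  (strict)
    k_min = np.floor((wx - r - band_m - params.row_offset_m) / d).astype(int) + 1
    k_max = np.ceil((wx + r - params.row_offset_m) / d).astype(int) - 1
    k_min = np.clip(k_min, 0, n_frames - 1)
    k_max = np.clip(k_max, -1, n_frames - 1)
    return np.maximum(0, k_max - k_min + 1)


def _n_frames(scene: FieldScene, params: SimParams, band_m: float) -> int:
    v = params.speed_kmh / 3.6
    return int(math.ceil((scene.length_m + band_m + 0.5) / (v / params.fps))) + 1


def simulate_pass(scene: FieldScene, params: SimParams, grille: GrilleConfig,
                  setup: CameraSetup, scale: GroundScale | None = None) -> SimResult:
    """Drive the boom over the scene and account for identifications and hits.

    Per frame, each weed whose projected box overlaps the grille band is
    detected with probability ``p_detect_effective`` and its box perturbed
    by the localization noise; the grille decision runs per camera, the
    decision vectors travel through the wire protocol, and the concatenated
    requests are rate-limited into the valve timeline.  A weed is
    *identified* when detected in at least one frame, and *hit* when its
    canopy centre lies inside a sprayed strip (vibration-displaced) of any
    lane.
    """
    if params.speed_kmh <= 0:
        raise ValueError("simulate_pass needs a positive forward speed")
    scale = scale or ground_scale(setup)
    warnings: list[str] = []
    motion = MotionProfile(params.speed_kmh, params.fps)
    if not check_grille_constraint(grille.row_height_px, scale, motion).passed:
        warnings.append(
            "grille band narrower than per-frame advance; misses are expected")
    rng = np.random.default_rng(derive_seed(params.seed, "pass"))
    v = params.speed_kmh / 3.6
    dt = 1.0 / params.fps
    px_m = scale.mm_per_px / 1000.0
    band_m = grille.row_height_px * px_m
    H, W = setup.image_height_px, setup.image_width_px
    boom_y0 = (scene.width_m - setup.boom_width_m) / 2
    n_valves = setup.n_cameras * grille.n_cells
    p_eff = params.p_detect_effective
    n_frames = _n_frames(scene, params, band_m)

    detected_frames: list[list[int]] = [[] for _ in range(scene.n_weeds)]
    requests: list[DecisionVector] = []
    for k in range(n_frames):
        x_nozzle = v * k * dt
        band_start = x_nozzle + params.row_offset_m
        cam_boxes: list[list[PredictionBox]] = [[] for _ in range(setup.n_cameras)]
        for i, (wx, wy, r) in enumerate(scene.weeds):
            if not (band_start < wx + r and wx - r < band_start + band_m):
                continue
            if rng.random() >= p_eff:
                continue
            detected_frames[i].append(k)
            noise = rng.normal(0.0, params.sigma_loc_mm / 1000.0, 2)
            cx_g, cy_g = wx + noise[0], wy + noise[1]
            cam = int((cy_g - boom_y0) // setup.camera_span_m)
            cam = min(max(cam, 0), setup.n_cameras - 1)
            cam_y0 = boom_y0 + cam * setup.camera_span_m
            col = (cy_g - cam_y0) / px_m
            row = H - (cx_g - x_nozzle - params.row_offset_m) / px_m
            r_px = r / px_m
            box = PredictionBox(col - r_px, row - r_px, col + r_px, row + r_px
                                ).clipped(W, H)
            if box is not None:
                cam_boxes[cam].append(box)
        bits: list[int] = []
        for cam in range(setup.n_cameras):
            vector = decide_frame(cam_boxes[cam], grille)
            decoded, err = decode_frame(encode_frame(vector))
            assert err is None
            bits.extend(decoded.bits)
        requests.append(DecisionVector(tuple(bits)))

    timeline = apply_rate_limit(requests, params.fps,
                                max_freq=params.max_valve_freq_hz,
                                min_open_s=params.min_open_s)
    # sprayed strips with per-interval vibration displacement
    latency = params.valve_latency_ms / 1000.0
    sigma_vib_m = params.sigma_vib_mm / 1000.0
    strips: list[list[tuple[float, float, float]]] = []  # (x0, x1, lateral_offset)
    for valve in range(n_valves):
        lane_strips = []
        for (t0, t1) in timeline.intervals[valve]:
            vib = rng.normal(0.0, sigma_vib_m, 2) if sigma_vib_m > 0 else (0.0, 0.0)
            x0 = v * (t0 + latency) - params.spray_margin_m / 2 + vib[0]
            x1 = v * (t1 + latency) + params.spray_margin_m / 2 + vib[0]
            lane_strips.append((x0, x1, vib[1]))
        strips.append(lane_strips)

    events: list[WeedEvent] = []
    n_identified = n_hit = 0
    for i, (wx, wy, r) in enumerate(scene.weeds):
        identified = bool(detected_frames[i])
        lane = int(np.clip((wy - boom_y0) // params.nozzle_spacing_m, 0, n_valves - 1))
        hit = False
        if identified:
            for j in range(n_valves):
                lane_y0 = boom_y0 + j * params.nozzle_spacing_m
                for x0, x1, dy in strips[j]:
                    if x0 <= wx < x1 and lane_y0 + dy <= wy < lane_y0 + params.nozzle_spacing_m + dy:
                        hit = True
                        break
                if hit:
                    break
        n_identified += identified
        n_hit += hit
        events.append(WeedEvent(i, wx, wy, r, lane, detected_frames[i],
                                identified, hit))
    counts = TrialCounts(scene.n_weeds, n_identified, n_hit)
    return SimResult(counts=counts, rates=rates_from_counts(counts),
                     events=events, timeline=timeline, warnings=warnings)


def coverage_map(timeline: ValveTimeline, params: SimParams
                 ) -> list[list[tuple[float, float]]]:
    """Deterministic sprayed ground strips per lane (no vibration).

    Each open interval ``[t0, t1)`` wets a longitudinal span of
    ``speed * (t1 - t0) + spray_margin_m`` centred on the interval's ground
    track; overlapping strips within a lane are merged.
    """
    v = params.speed_kmh / 3.6
    latency = params.valve_latency_ms / 1000.0
    out: list[list[tuple[float, float]]] = []
    for intervals in timeline.intervals:
        spans = sorted((v * (t0 + latency) - params.spray_margin_m / 2,
                        v * (t1 + latency) + params.spray_margin_m / 2)
                       for t0, t1 in intervals)
        merged: list[tuple[float, float]] = []
        for a, b in spans:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        out.append(merged)
    return out


def speed_sweep(scene: FieldScene, speeds: Sequence[float], params: SimParams,
                grille: GrilleConfig, setup: CameraSetup,
                n_seeds: int = 1) -> "pandas.DataFrame":
    """Run the pass at each speed with paired seeds; one report row per speed.

    With ``n_seeds > 1`` each speed is averaged over the same seed set
    (paired comparison), and the rate columns are means of the per-seed
    unrounded rates expressed as percentages.
    """
    import pandas as pd

    if len(speeds) < 2:
        raise ValueError("speed_sweep needs at least 2 speeds")
    records = []
    for speed in speeds:
        u_list, wrel_list, wabs_list = [], [], []
        last = None
        for s in range(n_seeds):
            p = replace(params, speed_kmh=speed, seed=derive_seed(params.seed, f"rep{s}"))
            last = simulate_pass(scene, p, grille, setup)
            u_list.append(last.rates.u)
            wrel_list.append(last.rates.w_rel)
            wabs_list.append(last.rates.w_abs)
        records.append({
            "speed_kmh": speed,
            "n_weeds": scene.n_weeds,
            "n_identified": last.counts.n_identified,
            "effective_recognition_rate_pct": 100 * float(np.mean(u_list)),
            "n_hits": last.counts.n_hit,
            "relative_hit_rate_pct": 100 * float(np.mean(wrel_list)),
            "absolute_hit_rate_pct": 100 * float(np.mean(wabs_list)),
        })
    return pd.DataFrame.from_records(records)
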