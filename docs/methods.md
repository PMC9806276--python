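# Methods

`spotspray` models the software chain of a machine-vision target sprayer: a
boom vehicle drives crop rows while downward cameras image the ground, a
lightweight single-stage detector finds weeds in each frame, a grid-cell
("grille") rule converts detection boxes into solenoid-valve commands, and
individually switched nozzles spray only where weeds are. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Geometry and calibration

The boom of width `B` (default 3.3 m) is split evenly between `n` cameras
(default 2) with no overlap; one camera images `B/n` of ground across `W`
pixels (default 1920), so one pixel covers

```
mm_per_px = (B / n) * 1000 / W          # 3.3 m, 2 cams, 1920 px -> 0.859375
```

The scale is carried unrounded internally; the 3-decimal value (0.859) is
what reports quote, and derived report figures (a 60 px grille row = 51.54 mm
of ground) intentionally use the rounded scale so printed numbers are
self-consistent. Mount height (1 m) is metadata only — the scale is fixed by
boom span over pixel width, not by an optics model; lens distortion and
perspective are out of scope.

**Real-time width constraint.** Decisions are re-evaluated once per frame,
so the grille row must cover more ground than the vehicle advances per
frame, `v / fps`. `check_grille_constraint` enforces the strict inequality
and reports the margin: at 4 km/h and 26.73 fps the advance is 41.57 mm
against a 51.54 mm row (margin ≈ 9.97 mm). The check is monotone in speed.

## Grille decision rule

A single row of `n_cells` cells (default 11 = half-boom 1.65 m at 0.15 m
nozzle spacing) tiles the image width exactly; integer division puts the
remainder pixels one-per-cell from the left, so cell widths differ by at
most one pixel (1920/11 → six 175s, five 174s). All rectangles are 0-based,
half-open. A cell's bit is set when some detection box of the weed class
overlaps it by **strictly more** than `area_threshold_px2`. Choices made
where the underlying rule is open:

* threshold default **0 px²** — any positive overlap sprays. This maximizes
  coverage redundancy, which is the stated purpose of a wide grille row;
  an absolute-area threshold is exposed in config (a fraction-of-cell-area
  interpretation is equivalent by rescaling).
* the row sits at the **bottom of the frame** (ground scrolls downward as
  the machine advances); `row_top_px` and a ground offset are configurable
  and default to 0, i.e. the grille row is taken to be the spray impact
  zone.
* decisions are **stateless per frame** — a bit falls back to 0 in the
  first frame whose boxes no longer clear the threshold (momentary-switch
  behaviour). No cross-frame tracking.

## Valve protocol and actuation limits

The wire format (start byte `0xAA`, valve count, LSB-first bit payload,
XOR checksum) is this package's own definition, documented bit-exactly so
independent implementations interoperate; the underlying system concept
only requires *some* serial frame. Decode errors are typed (start/length/
checksum) and a consumer holds the last good state for at most 3 bad frames
before failing safe to all-closed — also an invented, conservative policy.

Solenoid valves cycle at most `max_freq` = 10 Hz, and small weeds need a
base opening time, so raw per-frame requests are post-processed: every open
interval is extended to `min_open_s` (default 0.1 s, one full 10 Hz
period), and opens that would start within `1/max_freq` of the previous
open are merged (the valve stays open through the gap). Both operations
only ever add coverage, so sprayed ground is a superset of what was
requested — the safe direction for a herbicide hit-rate system.

## Detector

Architecture: MobileNetv3-Small backbone truncated at its stride-8/16/32
stages (published layer table; out-channels 24/48/96), an extra SE block
after each of the three outputs, an FPN top-down + PAN bottom-up neck
fusing levels by channel concatenation with depthwise-separable fuse
convolutions, and three 1×1 heads emitting `3 × (5 + n_classes)` channels
(18 for the single weed class). Heads decode YOLOv5-style
(`xy = (2σ−0.5+grid)·stride`, `wh = (2σ)²·anchor`). Open points resolved:

* **Small vs Large backbone**: Small, matching the few-MB model scale the
  design targets; the table is one list and swappable.
* **SE reduction**: 4 everywhere (MobileNetv3 convention); in-bottleneck SE
  reduces to the nearest divisor when the expansion width is not divisible.
* **Neck width**: one common width (default 48 channels) for all lateral
  projections and fused maps; concatenations are therefore 96 wide.
* Parameter count: ~0.91 M with defaults, asserted below a 4 M budget.

The whole network runs on an in-repo reverse-mode autograd over numpy
(im2col convolutions, exact batch-norm backward, stable BCE-with-logits);
every operator is verified against central finite differences in the test
suite. Float64 throughout; two forwards on the same weights are
bit-identical.

**Loss.** `λ1·L_cls + λ2·L_loc + λ3·L_obj` with defaults (0.5, 0.05, 1.0)
— single-stage convention; the balance coefficients are free parameters.
Positives are assigned across the grid cell (the containing cell plus
adjacent cells within half a cell of the centre) with an anchor ratio
filter (< 4). `L_loc` is mean `1 − IoU` of decoded boxes (a plain IoU loss;
CIoU-style terms add nothing at the toy scales this package trains at).
`L_obj` uses hard 0/1 targets; the IoU-soft variant is available
(`soft_obj_targets=True`) but soft labels bound the BCE away from zero and
are a poor fit for overfit-style convergence checks.

**Training.** Adam with cosine-annealed learning rate (`lr(0)=lr_max`,
`lr(T)=lr_min`; defaults 1e-2 → 5e-5 — the large network-relative peak is
what full-batch training of a small net on ≤10 images wants), fixed-seed
shuffling, and checkpoint selection as the lowest-loss epoch within the
final quarter of the schedule, after the rate has annealed. Training is
exercised at toy scale by design: 10 synthetic 96×96 images for 50 epochs
(~40 s single-core) must drop the loss to ≤ 10% of its initial value. This
checks that the architecture, loss, gradients and optimizer cooperate; it
says nothing about field accuracy on real imagery.

**Anchors** come from K-means under the `1 − IoU` distance with seeded
k-means++ initialization, mean updates, and empty clusters reseeded to the
farthest box; the 9 centroids are sorted by area, 3 per scale.
**Letterbox** scales the long side to the square input and pads the rest
with gray 114, returning the invertible affine for box remapping.
**Mosaic** splits a canvas at a random centre into four quadrants, fills
each with one anisotropically scaled sample, remaps and clips boxes, and
drops slivers under 2 px.

**Evaluation** is single-class at IoU 0.5 (confidence and NMS thresholds
0.5): greedy one-to-one matching in descending confidence, ties by input
order; `P`, `R` as percentages, `F1` their harmonic mean, and `AP` the
exact all-points area under the precision envelope with the PR curve swept
over *distinct* confidence thresholds — tied detections enter together,
which is what makes the area invariant to tie order. `TN` is carried in
the counts but enters no formula. Zero denominators yield 0 with a
degenerate flag.

## Spray accounting

For a trial strip with `N` weeds, `I` identified and `H` hit:
`u = I/N` (effective recognition rate), `w' = H/I` (relative hit rate),
`w = H/N = u·w'` (absolute hit rate). The product identity is exact on the
unrounded ratios. Printed percentages are **truncated** toward zero at two
decimals — the convention under which every entry of the reference
three-speed trial table reproduces exactly from its counts (half-up
rounding fails on two entries). `w'` of a trial with zero identifications
is defined as 0 with an explicit degenerate flag.

## Field-pass simulator

`generate_scene` draws a homogeneous spatial Poisson field (default
1.5 weeds/m² on a 20×3 m strip, matching the weed counts of a typical
trial strip) with log-normal canopy radii (median 3 cm, log-σ 0.3, clipped
to 0.5–20 cm — seedling-to-rosette sizes for a downward camera at ~1 m).
`render_frame` produces soil-textured frames with weeds as irregular green
blob unions plus shadow / wet-soil / overexposure styles, and exact
bounding boxes, for detector fixtures and VOC export.

`simulate_pass` advances the nozzle line at `v = speed/3.6` per second,
maps the grille row of each camera to its ground band, and per frame
detects each weed whose disc overlaps the band with probability
`p_detect_frame` (box centre perturbed by σ_loc). Decisions run through
the real grille code and the real wire protocol, are rate-limited, and
become sprayed strips: lane width = nozzle spacing, longitudinal span =
open duration × speed + redundancy margin, displaced by a per-interval
vibration offset drawn with σ_vib = σ0 × speed (default σ0 = 8 mm per
km/h — the explicit stand-in for "faster travel shakes the boom more").
A weed is *identified* if detected at least once and *hit* if identified
and its canopy centre lies inside any lane's sprayed strip (weeds
straddling lanes may be covered by a neighbour). Hits are counted only
among identified weeds so the count ordering `H ≤ I ≤ N` always holds;
incidental wetting of never-detected weeds is not credited.

Two mechanisms make rates fall with speed, both physical: fewer frames in
the band (smaller chance of any detection, and of a detection early enough
that the strip still covers the weed) and larger vibration displacement.
An optional per-km/h detection-quality penalty exists but defaults to 0.
Defaults reproduce the qualitative 2→4 km/h degradation; the simulator
makes no claim of matching any particular field trial's numbers, and the
camera-to-nozzle offset and valve latency default to 0 and are flagged in
logs when set.

What the synthetic world omits: real imagery (detection is a Bernoulli
draw, not a model inference), occlusion and clustering of weeds, terrain,
droplet drift and deposition physics. Passing simulator tests therefore
validates the decision/actuation/accounting chain, not field performance.

## Numerical and testing choices

* Strict inequalities at thresholds (grille area, constraint margin) so
  boundary cases are deterministic; exact integer tiling for cells.
* Grille overlap is validated against brute-force pixel rasterization on
  integer boxes (exact equality), the protocol against exhaustive 8-valve
  and 10,000 random round-trips, AP against an explicit threshold-sweep
  oracle, K-means against exhaustive partition search on small sets, and
  the simulator's identification count against the closed-form per-weed
  pass probability (95% normal CI over ≥ 500 weeds).
* One global seed fans out per stage through SHA-256 (`derive_seed`), so
  adding a stage never perturbs another stage's stream; derived seeds stay
  below 2³¹.
* Problem sizes in the test suite (96–320 px inputs, ≤ 50 epochs, 90 m
  simulated strips, 50 paired seeds per speed) are chosen so the full
  suite runs in a couple of minutes on one core while every claim above is
  still exercised end to end.

## Known limitations

Pure-numpy training is single-threaded and practical only at toy scale;
no GPU path. The detector is single-class. No cross-frame association of
boxes, no multi-row grilles, no per-cell thresholds. The wire protocol
carries one camera per frame (a camera-id extension byte is reserved but
disabled). Camera synchronization and overlap are not modeled.
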