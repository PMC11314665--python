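# Methods

This note documents the models and procedures implemented in
`gaitcontext`, the defaults chosen where the underlying study protocol
left the design open, and what the synthetic-data experiments do and do
not demonstrate.

## Walking-path model

The wearer's immediate forward path is a trapezoid in scene-camera pixel
coordinates, symmetric about the vertical midline, with its base on the
bottom frame row. Defaults (`PathConfig`):

| parameter | default | meaning |
|---|---|---|
| `base_width_fraction` | 0.50 | base = the middle 50% of the frame width |
| `top_width_fraction` | 0.15 | top edge width (perspective convergence) |
| `top_y_fraction` | 0.55 | top edge at 55% of frame height from the top |

The base fraction is the defining constant of the model; the top width
and height are not pinned down by any measurement — the defaults were
chosen once to give a plausible converging corridor on a head-mounted
camera and are exposed as configuration, not constants. The trapezoid
extends exactly to the bottom row (no margin): on a chest- or head-worn
camera the wearer's feet are at or below the frame edge, so the nearest
visible ground belongs to the path.

## Overlap detection

Per frame, three binary masks are compared: object (bounding box), path
(trapezoid) and gaze (a filled disc of radius 30 px, configurable, around
the gaze sample — eye-tracker vendors report a point, not an extent, and
~30 px approximates a foveal patch at typical scene-camera resolution).
An object is `in_path` / `gazed` when the corresponding mask AND is
non-empty.

Masks are built directly at the working resolution (default 200 × 200
cells) by coordinate scaling rather than by building frame-sized masks
and shrinking them: the contract is identical and the cost drops from
O(W·H) to O(200²) per shape. A cell is set when its full-frame pixel
footprint intersects the shape with positive area (floor on minima, ceil
on maxima — *outward rounding*). Consequences, verified by the test
suite:

- masks are supersets of the exact shapes, so a genuinely overlapping
  pair is never reported as disjoint (no false negatives, at any
  resolution);
- disagreements with full-resolution geometry are confined to
  *near-misses* narrower than one cell (≈ 5.4 px either axis at
  1088 × 1080); measured agreement on random scenes is ≥ 99%;
- growing a box can only add cells, so `in_path` is monotone in the box;
- at mask resolution equal to the frame resolution the verdicts coincide
  with per-pixel geometry exactly.

The bias direction is deliberate: in a fall-risk context a false alarm
costs a glance at the report, a miss costs an unexamined hazard. Missing
or invalid gaze samples yield `gazed = false` rather than an error, since
eye trackers drop samples routinely.

`attention_on_hazards` aggregates frame verdicts into fixed windows
(default 2 s) and reports, per window, the fraction of hazard-present
frames whose hazard was gazed; windows without hazards are undefined
(`None`), not zero — no attention is demanded where nothing demands it.
An *unattended hazard window* is a window with hazards present and a
gazed fraction of exactly zero. This aggregation is a convention of this
package, not a measured clinical quantity.

## Selective anonymization

Every detection whose class carries the `privacy` role is blurred inside
its bounding box with a k × k Gaussian (default k = 157); all other
pixels are untouched, which the tests check bit-exactly. Details:

- σ is derived from k by the common automatic convention
  σ = 0.3·((k−1)·0.5 − 1) + 0.8 unless given explicitly;
- the kernel is separable and truncated at radius (k−1)/2, matching a
  direct convolution with the normalized k × k kernel (oracle-checked to
  ±1 intensity level);
- the crop is padded by reflection at its own borders, so no pixel
  outside the ROI influences the blurred result and vice versa;
- overlapping privacy ROIs are blurred sequentially in detection order;
  their intersection is blurred at least once either way;
- any privacy detection is blurred regardless of confidence (threshold
  0): over-obscuring is the safe failure mode for privacy.

Blurring is smoothing, hence contractive: re-blurring a frame changes the
ROI less than the first application did. The filter works on image
arrays and directories of still frames; video containers and audio are
out of scope (audio is never ingested at all).

## Class taxonomy

The built-in taxonomy has 18 classes in 4 categories: room/environment
context (stairs, doorway, shower, sink, toilet, table, bed, signage,
vehicle), context + fall-risk (chair, animal, wet surface), fall-risk
(mat/rug/carpet, obstacle, raised kerb) and privacy (person, screen,
book). Roles are independent flags: a person is simultaneously context
(something to navigate around) and privacy (someone to blur). Class
names match case-insensitively after trimming; hazard logic keys on the
`fall_risk` role, anonymization on `privacy`. Whether a context-only
observation should ever *suppress* a hazard flag is an open question in
the underlying protocol; this package never suppresses.

## Gait analysis

**Bout segmentation.** Walking is separated from rest by thresholding the
moving standard deviation (0.5 s window) of the acceleration magnitude at
0.05 g; active periods closer than 0.3 s are merged and bouts shorter
than 3 s discarded. These four numbers reproduce the *role* of validated
free-living segmentation algorithms at desk scale and are all
configurable; they are not a validated clinical segmentation.

**Event detection.** Within a bout the vertical channel is mean-detrended
(removing gravity/orientation offset without an arbitrary filter choice),
integrated, and differentiated with a Gaussian-derivative kernel — the
continuous-wavelet smoothing family standard for L5 sensors. ICs are the
local minima of the result (equivalently, minima of the Gaussian-smoothed
vertical acceleration); FCs are the maxima after differentiating once
more. The smoothing scale is 0.05 × the step period, with the step
period estimated from the spectral peak in the 1.4–3 Hz locomotor band.
Two robustness rules matter in practice:

- *FC refractory window*: the twice-differentiated signal rings just
  after each heel strike; since a toe-off cannot occur that early in
  stance, FC candidates within 2.5 smoothing sigmas after an IC are
  rejected. FC candidates are ranked by peak height, not prominence —
  a true FC peak on the shoulder of the heel-strike transient has small
  prominence but full height.
- *Alternation enforcement*: the merged event sequence must alternate
  IC, FC, IC, FC, … starting with an IC; within any same-type run only
  the strongest event is kept, and leading FCs are dropped.

On synthetic signals IC timing is recovered essentially exactly (100%
within ±30 ms across tested configurations). FC timing carries a small
systematic early bias of the order of the effective smoothing width
(≈ 20–40 ms), which propagates to stance/swing *means* but cancels in
step and stride times and in all asymmetries. No claim of clinical FC
accuracy is made or needed for the temporal-asymmetry read-out.

**Temporal statistics.** With validated ICs t₁ < t₂ < … and interleaved
FCs: stepₖ = tₖ₊₁ − tₖ, strideₖ = tₖ₊₂ − tₖ, stanceₖ = (first FC after
tₖ₊₁) − tₖ, swingₖ = strideₖ − stanceₖ (exact by construction; the tests
assert bitwise equality). Each series is summarized by mean, population
STD and asymmetry = |mean(even k) − mean(odd k)|. A single L5 sensor
cannot label steps left/right, so alternating indices are the standard
proxy; for symmetric gait the asymmetry is identically zero, and the
absolute value makes the statistic invariant to which foot struck first.
Consistency: for symmetric gait, mean step = mean stride / 2 (e.g.
0.69 s stance + 0.41 s swing = 1.10 s stride = 2 × 0.55 s step).

## Fusion

Camera and IMU clocks are assumed pre-synchronized to a common epoch; a
constant `clock_offset` knob absorbs a known lag. A frame belongs to the
bout whose interval contains its (offset-corrected) timestamp, within
`tolerance` (default 0.05 s) at the edges; frames outside all bouts stay
unassigned, and each frame joins at most one bout (earliest wins when
tolerance makes intervals touch). Bouts with no video coverage keep
their gait fields with context marked absent rather than zero. The
report deliberately contains no fall-risk score: the package computes
the ingredients (gait variability/asymmetry and its environmental
context) and leaves interpretation to the reader.

## Synthetic data: what it emulates, what it does not

**Scenes** emulate annotated egocentric frames: 1088 × 1080 by default
(a typical eye-tracking scene camera), 1–4 class-labelled boxes per
frame sized 5–25% of the frame, a mean-reverting random-walk gaze
trajectory, and a per-frame probability (default 0.3) that one
fall-risk box is forced to intersect the path. Rendered frames draw
boxes as filled class-coloured rectangles over a seeded value-noise
background — textured deliberately, because blurring a constant region
is the identity and would make the privacy tests vacuous. Ground-truth
verdicts are computed analytically in continuous full-resolution
geometry (interval arithmetic against the trapezoid; clamp distance
against the gaze disc), sharing no code with the mask engine.

**Gait signals** emulate an L5 accelerometer at 100 Hz: gravity plus a
locomotor oscillation phase-locked to the planted ICs (minima at heel
strikes), a sharp negative Gaussian transient (50 ms width) at each IC
and a positive one at each FC, white sensor noise (default 0.1 m/s²),
and optional quiet-standing padding. FCₖ is planted at
ICₖ + 0.62 × strideₖ (a normal stance fraction), so the truth series
satisfy stance + swing = stride identically. Default step time 0.55 s
with 0.01 s STD matches a typical lab walk; the even/odd step offset
sets the true asymmetry exactly.

Passing these tests shows the *algorithms* are implemented correctly and
recover planted parameters under realistic noise; it does not validate
them against optoelectronic gait references, real cluttered scenes, or a
trained detector's error patterns. In particular the study's reported
detector quality (trained on private video) is not reproducible here —
the evaluation module is instead verified on enumerable cases, and the
replay backend substitutes a perfect detector so downstream logic is
testable end to end.

## Numerical choices and degenerate inputs

- Boxes are half-open pixel intervals `[x_min, x_max) × [y_min, y_max)`,
  0-based; converters from centre/width (YOLO) and 1-based inclusive
  corners (VOC) land on this convention, so areas and intersections are
  exact integer arithmetic. YOLO round-trips are exact to 1 px
  (normalization quantization).
- AP uses all-point interpolation (precision-envelope area) by default,
  with classic 11-point sampling behind a flag; mAP50 averages over
  classes with at least one ground-truth instance. Confidence ties are
  broken by input order (documented, deterministic).
- A shape entirely outside the frame rasterizes to an all-zero mask (not
  an error); a constant accelerometer signal yields zero gait events; a
  bout shorter than ~3 step periods is a `ValueError`.
- Problem sizes used by the checked experiments — 1000 scene frames for
  overlap agreement, 120 s walks for gait recovery, 100-frame episodes
  for the fused report — were chosen to give tight statistics (≈ 4000
  verdicts, ≈ 200 steps) while keeping any single check in the seconds
  range.

## Known limitations

- The walking path is a fixed frame-relative trapezoid: no ground-plane
  estimation, no depth, no compensation for head yaw. Objects above the
  ground (a wall sign over the path) can be flagged `in_path`.
- No object tracking: the same physical hazard in n frames counts n
  times in per-class frame counts.
- Overlap verdicts are resolution-limited: sub-cell near-misses may be
  flagged as overlaps (never the reverse).
- The gait module covers temporal characteristics only — no step length
  or velocity, no turning metrics, no freezing-of-gait detection.
- Asymmetry by alternating indices assumes no dropped steps; a missed IC
  swaps the parity of subsequent steps (the absolute value bounds the
  damage but does not remove it).
- The blur is not a formal irreversibility guarantee; it is the standard
  practical obscuration, applied conservatively.
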