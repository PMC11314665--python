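"""Synthetic scenes and gait signals with exact ground truth.

The real study data (egocentric video of people walking at home and
outdoors, plus lower-back IMU traces) cannot be shared, so every stage of
the pipeline is exercised against generators that *know* the answer:

* **Scenes** — frames carrying class-labelled rectangles, a smooth gaze
  trajectory, and optionally rendered images (textured background,
  coloured boxes) for the privacy filter.  The true in-path/gazed flag
  for every box is computed analytically in continuous full-resolution
  geometry — interval arithmetic against the trapezoid and the gaze
  disc — entirely independent of the mask-based engine under test.
* **Gait** — a vertical-axis locomotor oscillation phase-locked to
  planted initial-contact times, sharp Gaussian transients at each
  initial and final contact, white sensor noise, and optional rest
  padding.  The truth lists every planted event time and the implied
  step/stride/stance/swing series.

Truths are oracles, not echoes: nothing here calls the detection code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotations import AnnotationRecord
from .core import BoundingBox, Detection, FrameRecord, GazeSample
from .gait import G, AccelSignal
from .path_overlap import PathConfig, WalkingPath, build_walking_path
from .taxonomy import Taxonomy, is_hazard_class, load_taxonomy

# ---------------------------------------------------------------------------
# analytic overlap oracle (continuous geometry, full resolution)


def box_intersects_path(box: BoundingBox, path: WalkingPath) -> bool:
    """Positive-area intersection of a box with the path trapezoid.

    The horizontal overlap width between the box and the trapezoid is
    non-decreasing in y (the trapezoid widens downward), so a positive-
    area intersection exists iff the overlap width is positive at the
    lower end of the shared vertical span.
    """
    y_lo = max(box.y_min, path.top_y)
    y_hi = min(box.y_max, path.bottom_y)
    if y_hi <= y_lo:
        return False
    extent = path.x_extent_at(y_hi)
    if extent is None:
        return False
    left, right = extent
    return min(box.x_max, right) - max(box.x_min, left) > 0


def box_intersects_circle(box: BoundingBox, cx: float, cy: float, r: float) -> bool:
    """Positive-area intersection of a box with a disc (clamp distance)."""
    dx = max(box.x_min - cx, 0.0, cx - box.x_max)
    dy = max(box.y_min - cy, 0.0, cy - box.y_max)
    return dx * dx + dy * dy < r * r


def _point_segment_dist(px, py, ax, ay, bx, by) -> float:
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return math.hypot(px - ax, py - ay)
    t = max(0.0, min(1.0, ((px - ax) * vx + (py - ay) * vy) / L2))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def circle_intersects_path(cx: float, cy: float, r: float, path: WalkingPath) -> bool:
    """Positive-area intersection of the gaze disc with the trapezoid."""
    extent = path.x_extent_at(cy)
    if extent is not None and extent[0] < cx < extent[1]:
        return True
    verts = path.vertices
    d = min(
        _point_segment_dist(cx, cy, *verts[i], *verts[(i + 1) % 4]) for i in range(4)
    )
    return d < r


# ---------------------------------------------------------------------------
# scene generation


@dataclass
class SceneConfig:
    """Scene-sequence generator settings.

    Frame size defaults to the 1088 x 1080 scene camera of wearable
    eye-tracking glasses.  ``hazard_in_path_prob`` is the per-frame
    probability that one fall-risk-class box is forced to intersect the
    walking path; remaining boxes are placed uniformly at random.
    """

    width: int = 1088
    height: int = 1080
    n_frames: int = 100
    fps: float = 10.0
    time_offset: float = 0.0  # timestamp of frame 0, s
    boxes_per_frame: tuple[int, int] = (1, 4)
    box_size_range: tuple[float, float] = (0.05, 0.25)  # fractions of frame
    min_box_px: float = 20.0
    hazard_in_path_prob: float = 0.3
    gaze_radius: float = 30.0
    gaze_step_px: float = 25.0  # random-walk innovation scale
    gaze_dropout: float = 0.0  # probability a gaze sample is invalid
    path: PathConfig = field(default_factory=PathConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard_in_path_prob <= 1.0:
            raise ValueError("hazard_in_path_prob must be in [0, 1]")
        if self.box_size_range[0] <= 0:
            raise ValueError("box sizes must be positive")


@dataclass
class SceneTruth:
    """Per-frame ground truth computed by the analytic oracle."""

    verdicts: list[list[tuple[str, bool, bool]]]  # (class, in_path, gazed)
    hazard_in_path: list[bool]
    gaze_on_path: list[bool]
    hazard_gazed: list[bool]
    annotations: list[AnnotationRecord]


def _class_color(class_id: int) -> tuple[int, int, int]:
    return ((37 * class_id + 13) % 256, (91 * class_id + 50) % 256, (53 * class_id + 120) % 256)


def render_frame(record: FrameRecord, taxonomy: Taxonomy, seed: int = 0) -> np.ndarray:
    """Draw a frame: seeded value-noise background + filled class boxes.

    The textured background guarantees that blurring visibly changes
    pixels (a constant background would make blur the identity).
    """
    rng = np.random.default_rng(seed)
    coarse = rng.integers(40, 216, size=(16, 16, 3), dtype=np.uint8)
    reps_y = -(-record.height // 16)
    reps_x = -(-record.width // 16)
    img = np.kron(coarse, np.ones((reps_y, reps_x, 1), dtype=np.uint8))
    img = img[: record.height, : record.width].copy()
    jitter = rng.integers(0, 17, size=img.shape, dtype=np.uint8)
    img = (img.astype(np.int16) + jitter - 8).clip(0, 255).astype(np.uint8)
    for det in record.detections:
        b = det.box.clip(record.width, record.height)
        if b is None:
            continue
        color = _class_color(taxonomy.class_id(det.class_name))
        img[int(b.y_min): int(b.y_max), int(b.x_min): int(b.x_max)] = color
    return img


def _random_box(rng: np.random.Generator, cfg: SceneConfig) -> BoundingBox:
    smin, smax = cfg.box_size_range
    w = max(rng.uniform(smin, smax) * cfg.width, cfg.min_box_px)
    h = max(rng.uniform(smin, smax) * cfg.height, cfg.min_box_px)
    x0 = rng.uniform(0, cfg.width - w)
    y0 = rng.uniform(0, cfg.height - h)
    return BoundingBox(round(x0), round(y0), round(x0 + w), round(y0 + h))


def _hazard_box_in_path(
    rng: np.random.Generator, cfg: SceneConfig, path: WalkingPath
) -> BoundingBox:
    """A box guaranteed (by the analytic oracle) to intersect the path."""
    for _ in range(100):
        box = _random_box(rng, cfg)
        # drop it onto the lower half of the path, near the centreline
        w, h = box.width, box.height
        cx = cfg.width / 2 + rng.uniform(-0.1, 0.1) * cfg.width
        y1 = rng.uniform(0.8, 1.0) * cfg.height
        cand = BoundingBox(
            round(max(cx - w / 2, 0)),
            round(max(y1 - h, 0)),
            round(min(cx + w / 2, cfg.width)),
            round(min(y1, cfg.height)),
        )
        if box_intersects_path(cand, path):
            return cand
    raise RuntimeError("failed to place an in-path hazard box")


def generate_scene_sequence(
    config: SceneConfig = SceneConfig(),
    taxonomy: Optional[Taxonomy] = None,
    render: bool = False,
) -> tuple[list[FrameRecord], list[np.ndarray], SceneTruth]:
    """Generate frames + (optionally) rendered images + analytic truth.

    Deterministic under a fixed seed.  Truth verdicts are computed with
    the continuous-geometry oracle at full resolution, never with the
    mask engine.
    """
    tax = taxonomy or load_taxonomy("builtin")
    rng = np.random.default_rng(config.seed)
    path = build_walking_path(config.width, config.height, config.path)
    hazard_classes = [n for n in tax.names if is_hazard_class(tax, n)]
    all_classes = list(tax.names)

    frames: list[FrameRecord] = []
    images: list[np.ndarray] = []
    truth = SceneTruth([], [], [], [], [])

    gx, gy = config.width / 2.0, config.height * 0.7
    for i in range(config.n_frames):
        t = config.time_offset + i / config.fps
        # smooth gaze random walk, mean-reverting toward frame centre
        gx += 0.05 * (config.width / 2 - gx) + rng.normal(0, config.gaze_step_px)
        gy += 0.05 * (config.height * 0.6 - gy) + rng.normal(0, config.gaze_step_px)
        gx = float(np.clip(gx, 0, config.width - 1))
        gy = float(np.clip(gy, 0, config.height - 1))
        valid = bool(rng.random() >= config.gaze_dropout)
        gaze = GazeSample(timestamp=t, x=gx, y=gy, valid=valid)

        detections: list[Detection] = []
        force_hazard = rng.random() < config.hazard_in_path_prob
        if force_hazard:
            cls = hazard_classes[rng.integers(len(hazard_classes))]
            detections.append(Detection(cls, _hazard_box_in_path(rng, config, path)))
        n_extra = int(rng.integers(config.boxes_per_frame[0], config.boxes_per_frame[1] + 1))
        for _ in range(n_extra):
            cls = all_classes[rng.integers(len(all_classes))]
            detections.append(Detection(cls, _random_box(rng, config)))

        record = FrameRecord(
            index=i, timestamp=t, width=config.width, height=config.height,
            detections=detections, gaze=gaze,
        )
        frames.append(record)
        if render:
            images.append(render_frame(record, tax, seed=config.seed * 100003 + i))

        frame_verdicts = []
        hazard_in, hazard_gazed = False, False
        for det in detections:
            in_path = box_intersects_path(det.box, path)
            gazed = valid and box_intersects_circle(det.box, gx, gy, config.gaze_radius)
            frame_verdicts.append((det.class_name, in_path, gazed))
            if is_hazard_class(tax, det.class_name) and in_path:
                hazard_in = True
                if gazed:
                    hazard_gazed = True
        truth.verdicts.append(frame_verdicts)
        truth.hazard_in_path.append(hazard_in)
        truth.gaze_on_path.append(valid and circle_intersects_path(gx, gy, config.gaze_radius, path))
        truth.hazard_gazed.append(hazard_gazed)
        truth.annotations.append(
            AnnotationRecord(
                image_id=f"frame_{i:06d}",
                boxes=[(d.class_name, d.box) for d in detections],
            )
        )
    return frames, images, truth


# ---------------------------------------------------------------------------
# gait signal generation


@dataclass
class GaitSimConfig:
    """Synthetic lower-back gait-signal settings.

    Defaults match a typical lab walk: step time 0.55 s, stance 62% of
    the stride.  ``step_offset`` shifts even-indexed steps by +offset/2
    and odd-indexed by -offset/2, so the true step asymmetry (difference
    of alternating means) equals |offset|.
    """

    step_mean: float = 0.55  # s
    step_std: float = 0.01  # s
    step_offset: float = 0.0  # s; true asymmetry = |offset|
    stance_fraction: float = 0.62  # of stride
    duration: float = 60.0  # s of walking
    rest_padding: float = 0.0  # s of quiet standing before and after
    fs: float = 100.0  # Hz
    noise_std: float = 0.1  # m/s^2 white sensor noise
    pulse_width: float = 0.05  # s, full width (~4 sigma) of event transients
    ic_amplitude: float = 4.0  # m/s^2
    fc_amplitude: float = 3.0  # m/s^2
    osc_amplitude: float = 0.5  # m/s^2 locomotor oscillation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mean <= 0:
            raise ValueError("step_mean must be positive")
        if self.step_std > self.step_mean / 2:
            raise ValueError("degenerate config: step_std > step_mean / 2")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.duration < 10 * self.step_mean:
            raise ValueError("duration must cover at least 10 steps")


@dataclass
class GaitTruth:
    """Planted events and the series they imply."""

    ic_times: np.ndarray
    fc_times: np.ndarray
    bout_start: float
    bout_end: float
    step_times: np.ndarray
    stride_times: np.ndarray
    stance_times: np.ndarray
    swing_times: np.ndarray

    @property
    def step_mean(self) -> float:
        return float(self.step_times.mean())

    @property
    def step_asymmetry(self) -> float:
        s = self.step_times
        return float(abs(s[0::2].mean() - s[1::2].mean()))


def generate_gait_signal(config: GaitSimConfig = GaitSimConfig()) -> tuple[AccelSignal, GaitTruth]:
    """Simulate a lower-back acceleration trace with known gait events.

    Vertical channel = gravity + a locomotor oscillation phase-locked to
    the initial contacts + a sharp negative Gaussian transient at each
    IC and a positive one at each FC + white noise.  Final contacts are
    planted at ``IC_k + stance_fraction * stride_k``.
    """
    rng = np.random.default_rng(config.seed)
    walk_start = config.rest_padding
    walk_end = config.rest_padding + config.duration
    total = walk_end + config.rest_padding

    # plant initial contacts; a virtual IC one step before the walk makes
    # the contralateral final contact before the first recorded IC real
    ics = [walk_start + 0.3 * config.step_mean]
    k = 0
    while True:
        offset = config.step_offset / 2 if k % 2 == 0 else -config.step_offset / 2
        step = config.step_mean + offset + rng.normal(0, config.step_std)
        step = max(step, 0.2 * config.step_mean)
        nxt = ics[-1] + step
        if nxt > walk_end - 0.2:
            break
        ics.append(nxt)
        k += 1
    ic = np.array(ics)
    if ic.size < 10:
        raise ValueError("configuration yields fewer than 10 steps")

    ic_ext = np.concatenate([[ic[0] - config.step_mean], ic])
    strides_ext = np.empty(ic_ext.size)
    strides_ext[:-2] = ic_ext[2:] - ic_ext[:-2]
    strides_ext[-2:] = 2 * config.step_mean
    fc_ext = ic_ext + config.stance_fraction * strides_ext
    fc = fc_ext[fc_ext < walk_end]

    n = int(round(total * config.fs)) + 1
    t = np.arange(n) / config.fs
    v = np.full(n, G)
    walking = (t >= walk_start) & (t <= walk_end)

    # oscillation phase advances by one cycle per step, minima at the ICs
    phase = np.interp(t, ic, np.arange(ic.size), left=0.0, right=float(ic.size - 1))
    v[walking] -= config.osc_amplitude * np.cos(2 * np.pi * phase[walking])

    sig_p = config.pulse_width / 4.0
    for te in ic:
        lo, hi = np.searchsorted(t, [te - 5 * sig_p, te + 5 * sig_p])
        v[lo:hi] -= config.ic_amplitude * np.exp(-((t[lo:hi] - te) ** 2) / (2 * sig_p**2))
    for te in fc_ext:
        if not walk_start <= te <= walk_end:
            continue
        lo, hi = np.searchsorted(t, [te - 5 * sig_p, te + 5 * sig_p])
        v[lo:hi] += config.fc_amplitude * np.exp(-((t[lo:hi] - te) ** 2) / (2 * sig_p**2))

    ap = np.zeros(n)
    ap[walking] = 0.4 * config.osc_amplitude * np.sin(2 * np.pi * phase[walking] / 2.0)
    ml = np.zeros(n)
    if config.noise_std > 0:
        v += rng.normal(0, config.noise_std, n)
        ap += rng.normal(0, config.noise_std, n)
        ml += rng.normal(0, config.noise_std, n)

    steps = np.diff(ic)
    strides = ic[2:] - ic[:-2]
    stance_full = config.stance_fraction * strides_ext[1:]  # stance of each real IC
    m = strides.size
    stances = stance_full[:m]
    swings = strides - stances
    truth = GaitTruth(
        ic_times=ic,
        fc_times=fc,
        bout_start=walk_start,
        bout_end=walk_end,
        step_times=steps,
        stride_times=strides,
        stance_times=stances,
        swing_times=swings,
    )
    return AccelSignal(t, v, ap, ml), truth
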