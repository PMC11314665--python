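"""Core geometric and frame-level domain types.

Conventions used throughout the package:

* Pixel coordinates are 0-based.  A bounding box spans the half-open
  intervals ``[x_min, x_max) x [y_min, y_max)``, so its pixel area is
  ``(x_max - x_min) * (y_max - y_min)`` with no off-by-one ambiguity.
* Timestamps are seconds on a shared clock (scene camera, eye tracker and
  IMU are assumed synchronized up to a configurable constant offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box over half-open pixel intervals.

    ``[x_min, x_max) x [y_min, y_max)`` with 0-based pixel coordinates.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, frame_width: float, frame_height: float) -> Optional["BoundingBox"]:
        """Clip to the frame; ``None`` when nothing remains inside."""
        x0 = max(self.x_min, 0.0)
        y0 = max(self.y_min, 0.0)
        x1 = min(self.x_max, frame_width)
        y1 = min(self.y_max, frame_height)
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1)

    def intersection(self, other: "BoundingBox") -> Optional["BoundingBox"]:
        x0 = max(self.x_min, other.x_min)
        y0 = max(self.y_min, other.y_min)
        x1 = min(self.x_max, other.x_max)
        y1 = min(self.y_max, other.y_max)
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1)


@dataclass(frozen=True)
class Detection:
    """A single detected object in one frame."""

    class_name: str
    box: BoundingBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class GazeSample:
    """Scene-camera gaze coordinate at one instant.

    ``valid`` is false when the eye tracker dropped the sample or the gaze
    fell off the scene frame; downstream overlap logic treats invalid gaze
    as "not looking at anything" rather than an error.
    """

    timestamp: float
    x: float
    y: float
    valid: bool = True


@dataclass
class FrameRecord:
    """One scene-camera frame: detections plus the matching gaze sample."""

    index: int
    timestamp: float
    width: int
    height: int
    detections: list[Detection] = field(default_factory=list)
    gaze: Optional[GazeSample] = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")


def validate_sequence(frames: Sequence[FrameRecord]) -> None:
    """Check that frame timestamps are non-decreasing."""
    for a, b in zip(frames, frames[1:]):
        if b.timestamp < a.timestamp:
            raise ValueError(
                f"frame timestamps decrease at index {b.index}: "
                f"{a.timestamp} -> {b.timestamp}"
            )
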