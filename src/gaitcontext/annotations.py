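"""Annotation/detection file I/O, dataset splitting, detector backends.

Two on-disk dialects are supported, matching what common labelling tools
emit:

* YOLO text — one line per box, ``class_id cx cy w h``, centre/size
  normalized to [0, 1] by the image dimensions;
* VOC XML — corner pixels ``xmin ymin xmax ymax`` (1-based inclusive,
  as written by LabelImg), converted on read to this package's 0-based
  half-open convention.

A minimal detector-backend contract lets the pipeline run without any
trained network: the bundled :class:`AnnotationReplayBackend` replays
ground-truth annotation files as detections with confidence 1.0, and any
object with a ``detect(image) -> list[Detection]`` method can be dropped
in instead.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, TypeVar, Union

from lxml import etree

from .core import BoundingBox, Detection
from .taxonomy import Taxonomy


@dataclass
class AnnotationRecord:
    """All labelled boxes for one image; confidences absent for ground truth."""

    image_id: str
    boxes: list[tuple[str, BoundingBox]] = field(default_factory=list)
    confidences: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.confidences is not None and len(self.confidences) != len(self.boxes):
            raise ValueError("confidences length must match boxes")

    def to_detections(self, default_confidence: float = 1.0) -> list[Detection]:
        confs = self.confidences or [default_confidence] * len(self.boxes)
        return [
            Detection(class_name=name, box=box, confidence=c)
            for (name, box), c in zip(self.boxes, confs)
        ]


def yolo_line_to_box(
    line: str, image_width: int, image_height: int, class_names: Sequence[str]
) -> tuple[str, BoundingBox, Optional[float]]:
    """Parse one YOLO-txt line into (class name, pixel box, confidence).

    The optional sixth field is a detection confidence (YOLO prediction
    dumps include it; ground-truth files do not).
    """
    parts = line.split()
    if len(parts) not in (5, 6):
        raise ValueError(f"malformed YOLO line: {line!r}")
    class_id = int(parts[0])
    cx, cy, w, h = (float(p) for p in parts[1:5])
    for v, name in ((cx, "cx"), (cy, "cy"), (w, "w"), (h, "h")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"YOLO {name}={v} outside [0, 1] in line {line!r}")
    if not 0 <= class_id < len(class_names):
        raise ValueError(f"unknown class id {class_id} (have {len(class_names)} classes)")
    x_min = round((cx - w / 2.0) * image_width)
    x_max = round((cx + w / 2.0) * image_width)
    y_min = round((cy - h / 2.0) * image_height)
    y_max = round((cy + h / 2.0) * image_height)
    x_min, x_max = max(x_min, 0), min(x_max, image_width)
    y_min, y_max = max(y_min, 0), min(y_max, image_height)
    conf = float(parts[5]) if len(parts) == 6 else None
    return class_names[class_id], BoundingBox(x_min, y_min, x_max, y_max), conf


def read_annotations(
    path: Union[str, Path],
    fmt: str,
    image_dims: Optional[tuple[int, int]] = None,
    class_names: Optional[Sequence[str]] = None,
) -> AnnotationRecord:
    """Read one image's annotations from a YOLO-txt or VOC-XML file.

    YOLO requires ``image_dims=(width, height)`` and ``class_names`` (the
    taxonomy's ordered names) to denormalize; VOC carries both in the XML.
    """
    path = Path(path)
    if fmt == "yolo_txt":
        if image_dims is None or class_names is None:
            raise ValueError("yolo_txt requires image_dims and class_names")
        w, h = image_dims
        boxes: list[tuple[str, BoundingBox]] = []
        confs: list[float] = []
        has_conf = False
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            name, box, conf = yolo_line_to_box(line, w, h, class_names)
            boxes.append((name, box))
            if conf is not None:
                has_conf = True
            confs.append(conf if conf is not None else 1.0)
        return AnnotationRecord(
            image_id=path.stem, boxes=boxes, confidences=confs if has_conf else None
        )
    elif fmt == "voc_xml":
        return _read_voc(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_voc(path: Path) -> AnnotationRecord:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML {path}: {exc}") from exc
    root = tree.getroot()
    image_id = root.findtext("filename") or path.stem
    boxes: list[tuple[str, BoundingBox]] = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        bb = obj.find("bndbox")
        if name is None or bb is None:
            raise ValueError(f"VOC object missing name/bndbox in {path}")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmax < xmin or ymax < ymin:
            raise ValueError(f"inverted VOC box in {path}: {(xmin, ymin, xmax, ymax)}")
        # VOC corners are 1-based inclusive; shift to 0-based half-open
        boxes.append((name, BoundingBox(xmin - 1, ymin - 1, xmax, ymax)))
    return AnnotationRecord(image_id=Path(image_id).stem, boxes=boxes)


def write_annotations(
    record: AnnotationRecord,
    path: Union[str, Path],
    fmt: str,
    image_dims: Optional[tuple[int, int]] = None,
    class_names: Optional[Sequence[str]] = None,
) -> None:
    """Write annotations; YOLO normalization quantizes boxes by < 1 px."""
    path = Path(path)
    if fmt != "yolo_txt":
        raise ValueError(f"unsupported write format {fmt!r}")
    if image_dims is None or class_names is None:
        raise ValueError("yolo_txt requires image_dims and class_names")
    w, h = image_dims
    index = {n.strip().lower(): i for i, n in enumerate(class_names)}
    lines = []
    confs = record.confidences
    for i, (name, box) in enumerate(record.boxes):
        cid = index[name.strip().lower()]
        cx = (box.x_min + box.x_max) / 2.0 / w
        cy = (box.y_min + box.y_max) / 2.0 / h
        bw = box.width / w
        bh = box.height / h
        line = f"{cid} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}"
        if confs is not None:
            line += f" {confs[i]:.6f}"
        lines.append(line)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


T = TypeVar("T")


def split_dataset(items: Sequence[T], ratio: float = 0.8, seed: int = 0) -> tuple[list[T], list[T]]:
    """Deterministic train/validation partition.

    Shuffles with the given seed and takes ``round(ratio * N)`` items for
    training; the partition is disjoint and exhaustive.
    """
    if not items:
        raise ValueError("cannot split an empty item list")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    order = list(items)
    random.Random(seed).shuffle(order)
    n_train = round(ratio * len(order))
    return order[:n_train], order[n_train:]


class DetectorBackend(Protocol):
    """Contract for pluggable object detectors."""

    def detect(self, image_id: str) -> list[Detection]: ...


class AnnotationReplayBackend:
    """Replays annotation files as detections with confidence 1.0.

    Lets the full contextualization/privacy pipeline run with no trained
    network: any directory of YOLO-txt or VOC-XML files acts as a
    perfect-recall detector.
    """

    def __init__(
        self,
        directory: Union[str, Path],
        fmt: str,
        taxonomy: Taxonomy,
        image_dims: Optional[tuple[int, int]] = None,
    ) -> None:
        self.directory = Path(directory)
        self.fmt = fmt
        self.taxonomy = taxonomy
        self.image_dims = image_dims
        self.suffix = ".txt" if fmt == "yolo_txt" else ".xml"

    def detect(self, image_id: str) -> list[Detection]:
        path = self.directory / f"{image_id}{self.suffix}"
        if not path.exists():
            return []
        record = read_annotations(
            path, self.fmt, image_dims=self.image_dims, class_names=self.taxonomy.names
        )
        return record.to_detections(default_confidence=1.0)
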