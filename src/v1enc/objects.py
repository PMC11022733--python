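"""Object-location channels: merging per-image detections into one covering
box and converting it to the normalized center-size (YOLO) representation
that enters the encoder as four constant input channels.

The object detector itself is an external tool; this module only consumes a
detections table. Coordinates are pixel-valued with the origin at the
bottom-left corner of the image; the center/size representation is invariant
to that choice of origin for ``w``/``h`` and symmetric for the centers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable

log = logging.getLogger(__name__)

#: Default stimulus dimensions (SENSORIUM monitors: 256 wide x 144 high).
IMAGE_WIDTH = 256
IMAGE_HEIGHT = 144


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box given by bottom-left (xL, yL) and top-right (xR, yR)
    pixel corners."""

    xL: float
    yL: float
    xR: float
    yR: float

    def validate(self, width: float = IMAGE_WIDTH, height: float = IMAGE_HEIGHT) -> None:
        if not (0.0 <= self.xL <= self.xR <= width):
            raise ValueError(f"invalid x extent {self.xL}..{self.xR} for width {width}")
        if not (0.0 <= self.yL <= self.yR <= height):
            raise ValueError(f"invalid y extent {self.yL}..{self.yR} for height {height}")


@dataclass(frozen=True)
class YoloBox:
    """Center-size box as unitless fractions of image width/height."""

    x: float
    y: float
    w: float
    h: float


def merge_boxes(
    boxes: Iterable[BoundingBox],
    pad_frac: float = 0.0,
    width: float = IMAGE_WIDTH,
    height: float = IMAGE_HEIGHT,
) -> BoundingBox:
    """Merge all detections of one image into a single covering box.

    The merged box spans the elementwise min/max of the input corners,
    optionally padded by ``pad_frac`` of each image dimension and clamped to
    the image bounds. Raises ``ValueError`` on an empty list; callers that
    can see zero detections should use :func:`fallback_box`.
    """
    boxes = list(boxes)
    if not boxes:
        raise ValueError("merge_boxes requires at least one box; use fallback_box() for images without detections")
    pad_x = pad_frac * width
    pad_y = pad_frac * height
    xL = max(0.0, min(b.xL for b in boxes) - pad_x)
    yL = max(0.0, min(b.yL for b in boxes) - pad_y)
    xR = min(float(width), max(b.xR for b in boxes) + pad_x)
    yR = min(float(height), max(b.yR for b in boxes) + pad_y)
    return BoundingBox(xL, yL, xR, yR)


def to_yolo(
    box: BoundingBox,
    width: float = IMAGE_WIDTH,
    height: float = IMAGE_HEIGHT,
) -> YoloBox:
    """Convert a corner box to normalized center-size form:
    x = ((xL+xR)/2)/width, y = ((yL+yR)/2)/height, w = (xR-xL)/width,
    h = (yR-yL)/height. Zero-area boxes are allowed but logged."""
    w = (box.xR - box.xL) / width
    h = (box.yR - box.yL) / height
    if w == 0.0 or h == 0.0:
        log.warning("zero-area bounding box %s", box)
    return YoloBox(
        x=(box.xL + box.xR) / 2.0 / width,
        y=(box.yL + box.yR) / 2.0 / height,
        w=w,
        h=h,
    )


def from_yolo(box: YoloBox, width: float = IMAGE_WIDTH, height: float = IMAGE_HEIGHT) -> BoundingBox:
    """Inverse of :func:`to_yolo` (corner reconstruction)."""
    half_w = box.w * width / 2.0
    half_h = box.h * height / 2.0
    cx = box.x * width
    cy = box.y * height
    return BoundingBox(cx - half_w, cy - half_h, cx + half_w, cy + half_h)


def fallback_box() -> YoloBox:
    """Whole-image box used when an image has no detections: the full frame
    is treated as the object so the four object channels stay well defined."""
    return YoloBox(0.5, 0.5, 1.0, 1.0)


def load_detections(path, confidence_threshold: float = 0.0) -> dict[str, list[BoundingBox]]:
    """Read a detections table and group boxes by image.

    The file is CSV with header ``image_id,class,confidence,xL,yL,xR,yR``;
    coordinates are pixels with a bottom-left origin. Rows whose confidence
    falls below ``confidence_threshold`` are dropped. A malformed row raises
    ``ValueError`` naming its line number.
    """
    expected = ["image_id", "class", "confidence", "xL", "yL", "xR", "yR"]
    out: dict[str, list[BoundingBox]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return out
        if [c.strip() for c in header] != expected:
            raise ValueError(f"detections file must have header {','.join(expected)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(expected):
                raise ValueError(f"line {lineno}: expected {len(expected)} fields, got {len(row)}")
            try:
                conf = float(row[2])
                box = BoundingBox(*(float(v) for v in row[3:7]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if conf < confidence_threshold:
                continue
            out.setdefault(row[0], []).append(box)
    return out


def image_yolo_box(
    boxes: list[BoundingBox],
    pad_frac: float = 0.0,
    width: float = IMAGE_WIDTH,
    height: float = IMAGE_HEIGHT,
) -> YoloBox:
    """Merged+converted box for one image, falling back to the whole frame
    when there are no detections."""
    if not boxes:
        return fallback_box()
    return to_yolo(merge_boxes(boxes, pad_frac=pad_frac, width=width, height=height), width, height)
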