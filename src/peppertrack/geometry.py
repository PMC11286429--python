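"""Bounding-box primitives shared by the whole pipeline.

Boxes live in continuous pixel coordinates with the image origin at the
top-left corner, x increasing rightward and y downward.  Externally (MOT
files, detector output) boxes are top-left/width/height ("tlwh"); inside
the motion filter they are center-x/center-y/aspect/height ("xyah"), the
measurement parameterization of the constant-velocity Kalman model.
No rounding happens inside the pipeline; serialization rounds to two
decimals at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidBoxError(ValueError):
    """Raised when a box with non-positive width or height enters an operation."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner plus size, in pixels.

    width and height must be strictly positive for any box accepted
    into the pipeline; degenerate detector output is dropped at ingest.
    """

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidBoxError(
                f"box must have positive size, got width={self.width}, height={self.height}"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_tlwh(self) -> np.ndarray:
        return np.array([self.left, self.top, self.width, self.height], dtype=float)


def tlwh_to_xyah(box: BoundingBox) -> np.ndarray:
    """Convert a box to the (center-x, center-y, aspect, height) measurement vector.

    aspect = width / height.  Inverse of :func:`xyah_to_tlwh` up to
    floating tolerance.
    """
    cx = box.left + box.width / 2.0
    cy = box.top + box.height / 2.0
    return np.array([cx, cy, box.width / box.height, box.height], dtype=float)


def xyah_to_tlwh(xyah: np.ndarray) -> BoundingBox:
    """Convert an (cx, cy, a, h) vector back to a top-left/size box."""
    cx, cy, a, h = (float(v) for v in np.asarray(xyah, dtype=float)[:4])
    w = a * h
    return BoundingBox(left=cx - w / 2.0, top=cy - h / 2.0, width=w, height=h)


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]; 0 when disjoint.

    Areas are computed from the same edge coordinates as the
    intersection so that identical boxes give exactly 1.0 regardless of
    floating-point cancellation in ``left + width``.
    """
    ra, rb = box_a.left + box_a.width, box_b.left + box_b.width
    ba, bb = box_a.top + box_a.height, box_b.top + box_b.height
    iw = min(ra, rb) - max(box_a.left, box_b.left)
    ih = min(ba, bb) - max(box_a.top, box_b.top)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (ra - box_a.left) * (ba - box_a.top)
    area_b = (rb - box_b.left) * (bb - box_b.top)
    union = area_a + area_b - inter
    return float(min(1.0, inter / union))


def iou_matrix(boxes_a: list[BoundingBox], boxes_b: list[BoundingBox]) -> np.ndarray:
    """Pairwise IOU, rows indexing boxes_a."""
    out = np.zeros((len(boxes_a), len(boxes_b)), dtype=float)
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            out[i, j] = iou(a, b)
    return out


def normalized_center_distance(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Euclidean center distance divided by the mean of the two box diagonals.

    Scale-free position discrepancy: 0 iff the centers coincide, ~1 when
    the centers are one average-box-diagonal apart.  Used by the offline
    position/shape verification of segment merging.
    """
    (ax, ay), (bx, by) = box_a.center, box_b.center
    dist = float(np.hypot(ax - bx, ay - by))
    mean_diag = 0.5 * (box_a.diagonal + box_b.diagonal)
    return dist / mean_diag
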