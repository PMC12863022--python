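"""Geometric localization of the middle-meatus (MM) region.

The MM is frequently hidden behind the middle turbinate (MT) or occluded,
so the algorithm infers its region from the detected landmarks instead of
segmenting it directly:

* **primary** (MT and IT both detected): the region hangs off the medial
  MT edge, from ``delta_y`` px above the MT top down to the top of the
  inferior turbinate, spanning ``delta_x`` px horizontally.
* **fallback** (IT undetected — occlusion, image quality, IT out of
  frame): the vertical extent is derived from the MT alone (by default
  extended to ``y_MTbottom + 0.5 * h_MT``) and the horizontal span shrinks
  to the conservative ``delta_x_safe``.

Offsets were calibrated at the native 1024x768 resolution and are scaled
proportionally for other frame sizes. The horizontal span extends from the
medial MT edge toward the septum (decreasing x in a right cavity,
increasing x in a left cavity) by default; ``mm_direction="lateral"``
flips it for users who prefer the anatomically lateral interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .geometry import (
    BoundingBox,
    Laterality,
    medial_edge_x,
    vertical_extent,
)
from .io import AlgorithmConfig, ClassLabel, Detection
from .io import NATIVE_HEIGHT, NATIVE_WIDTH

__all__ = ["MMRegion", "locate_mm", "best_instance"]


@dataclass(frozen=True)
class MMRegion:
    """Computed middle-meatus box with its construction method.

    ``method`` is ``"primary"`` (MT+IT), ``"fallback"`` (MT only) or
    ``"failed"`` (no MT, inconsistent anatomy, or the box degenerated at a
    frame border); ``box`` is None exactly when the method is failed.
    """

    box: BoundingBox | None
    method: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if (self.method == "failed") != (self.box is None):
            raise ValueError("failed regions have no box; others must carry one")

    @property
    def ok(self) -> bool:
        return self.method != "failed"


_FAILED = MMRegion(box=None, method="failed")


def best_instance(
    detections: Sequence[Detection], label: ClassLabel
) -> Detection | None:
    """Highest-confidence instance of a class; ties broken by larger area, then order."""
    candidates = [
        (d.confidence, d.instance_area, -i, d)
        for i, d in enumerate(detections)
        if d.label == label
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda t: t[:3])[3]


def _edges(det: Detection, side: Laterality) -> tuple[float, float, float, float]:
    """Medial-edge x and vertical extent, from the mask when available else the box."""
    if det.mask is not None:
        e = medial_edge_x(det.mask, side)
        y_top, y_bottom, h = vertical_extent(det.mask)
    else:
        e = det.box.x1 if side is Laterality.RIGHT else det.box.x2
        y_top, y_bottom, h = det.box.y1, det.box.y2, det.box.height
    return e, y_top, y_bottom, h


def locate_mm(
    mt: Detection | None,
    it: Detection | None,
    side: Laterality,
    width: float,
    height: float,
    cfg: AlgorithmConfig | None = None,
) -> MMRegion:
    """Locate the middle-meatus region from the MT (and optionally IT) landmarks.

    Returns a failed region when no MT is available, when the IT top lies
    above the region's upper bound (inconsistent anatomy), or when clamping
    to the frame leaves no area.
    """
    cfg = cfg or AlgorithmConfig()
    side = Laterality.parse(side)
    if mt is None:
        return _FAILED

    sx = width / NATIVE_WIDTH
    sy = height / NATIVE_HEIGHT
    e, y_top, y_bottom, h = _edges(mt, side)

    if it is not None:
        dx = cfg.delta_x * sx
        y1 = max(y_top - cfg.delta_y * sy, 0.0)
        y2 = _edges(it, side)[1]  # top of the inferior turbinate
        method = "primary"
    else:
        dx = cfg.delta_x_safe * sx
        if cfg.fallback_y_rule == "extended":
            y1 = max(y_top - cfg.delta_y * sy, 0.0)
            y2 = y_bottom + 0.5 * h
        else:  # strict_mt: the MT extent itself bounds the region vertically
            y1, y2 = y_top, y_bottom
        method = "fallback"

    if y2 <= y1:
        return _FAILED

    inward = side is Laterality.RIGHT
    if cfg.mm_direction == "lateral":
        inward = not inward
    if inward:
        x1, x2 = e - dx, e
    else:
        x1, x2 = e, e + dx
    if x2 <= x1:  # zero horizontal offset collapses the box
        return _FAILED

    raw = BoundingBox(x1, y1, x2, y2)
    clamped_box, clamped = raw.clamp(width, height)
    # the printed max(y_MTtop - delta_y, 0) clip counts as clamping too
    clamped = clamped or (it is not None or cfg.fallback_y_rule == "extended") and (
        y_top - cfg.delta_y * sy < 0.0
    )
    if clamped_box is None:
        return _FAILED
    return MMRegion(box=clamped_box, method=method, clamped=bool(clamped))
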