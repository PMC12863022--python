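"""Pixel-space geometry primitives.

Coordinates are continuous, 0-based, origin at the top-left of the frame,
x increasing rightward and y increasing downward — the convention used by
COCO-style and YOLO-style annotation formats. Boxes are closed intervals
``[x1, x2] x [y1, y2]`` with area ``(x2 - x1) * (y2 - y1)``.

Polygon masks keep their vertex lists; edge coordinates (medial edge,
vertical extent) are computed directly from vertices rather than from a
rasterization, so results are deterministic and resolution-independent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "Laterality",
    "BoundingBox",
    "PolygonMask",
    "iou_boxes",
    "mask_to_box",
    "medial_edge_x",
    "vertical_extent",
]


class GeometryError(ValueError):
    """Raised for degenerate or malformed geometry."""


class Laterality(str, enum.Enum):
    """Side of the nasal cavity imaged; required metadata, never inferred."""

    LEFT = "left"
    RIGHT = "right"

    @classmethod
    def parse(cls, value: "str | Laterality") -> "Laterality":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise GeometryError(
                f"laterality must be 'left' or 'right', got {value!r}"
            ) from None

    @property
    def opposite(self) -> "Laterality":
        return Laterality.LEFT if self is Laterality.RIGHT else Laterality.RIGHT


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with ``x2 > x1`` and ``y2 > y1`` (strictly positive area)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise GeometryError(
                f"degenerate box ({self.x1}, {self.y1}, {self.x2}, {self.y2}): "
                "x2 must exceed x1 and y2 must exceed y1"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    def intersection_area(self, other: "BoundingBox") -> float:
        iw = min(self.x2, other.x2) - max(self.x1, other.x1)
        ih = min(self.y2, other.y2) - max(self.y1, other.y1)
        if iw <= 0.0 or ih <= 0.0:
            return 0.0
        return iw * ih

    def clamp(self, width: float, height: float) -> "tuple[BoundingBox | None, bool]":
        """Clip to ``[0, width] x [0, height]``.

        Returns ``(box, clamped)``; ``box`` is ``None`` when clipping leaves
        no area (the box lay outside the frame or collapsed to a line).
        """
        x1 = min(max(self.x1, 0.0), width)
        y1 = min(max(self.y1, 0.0), height)
        x2 = min(max(self.x2, 0.0), width)
        y2 = min(max(self.y2, 0.0), height)
        clamped = (x1, y1, x2, y2) != self.as_tuple()
        if x2 <= x1 or y2 <= y1:
            return None, clamped
        return BoundingBox(x1, y1, x2, y2), clamped

    def mirrored(self, width: float) -> "BoundingBox":
        """Reflection about the frame's vertical midline."""
        return BoundingBox(width - self.x2, self.y1, width - self.x1, self.y2)


def _shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class PolygonMask:
    """Closed simple polygon, optionally with several parts for fragmented instances.

    Each part is an ordered vertex ring with at least three vertices and
    non-zero enclosed area; the closing edge is implicit.
    """

    parts: tuple[tuple[tuple[float, float], ...], ...]

    def __post_init__(self) -> None:
        if not self.parts:
            raise GeometryError("mask has no parts")
        for part in self.parts:
            if len(part) < 3:
                raise GeometryError(
                    f"mask part has {len(part)} vertices; at least 3 required"
                )
            arr = np.asarray(part, dtype=float)
            # collinear rings can carry float-noise shoelace area; require
            # genuine extent on both axes as well
            if (
                _shoelace_area(arr) <= 0.0
                or np.ptp(arr[:, 0]) <= 0.0
                or np.ptp(arr[:, 1]) <= 0.0
            ):
                raise GeometryError("mask part encloses zero area")

    @classmethod
    def from_vertices(
        cls, vertices: Iterable[Sequence[float]]
    ) -> "PolygonMask":
        part = tuple((float(x), float(y)) for x, y in vertices)
        return cls(parts=(part,))

    @classmethod
    def from_parts(
        cls, parts: Iterable[Iterable[Sequence[float]]]
    ) -> "PolygonMask":
        return cls(
            parts=tuple(
                tuple((float(x), float(y)) for x, y in part) for part in parts
            )
        )

    def all_vertices(self) -> np.ndarray:
        """All vertices of all parts, stacked as an ``(n, 2)`` array."""
        return np.concatenate([np.asarray(p, dtype=float) for p in self.parts])

    @property
    def area(self) -> float:
        return float(sum(_shoelace_area(np.asarray(p, float)) for p in self.parts))

    def mirrored(self, width: float) -> "PolygonMask":
        return PolygonMask(
            parts=tuple(
                tuple((width - x, y) for x, y in part) for part in self.parts
            )
        )

    def translated(self, dx: float, dy: float) -> "PolygonMask":
        return PolygonMask(
            parts=tuple(
                tuple((x + dx, y + dy) for x, y in part) for part in self.parts
            )
        )


def iou_boxes(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes: ``|a∩b| / |a∪b|`` in [0, 1]."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union


def mask_to_box(mask: PolygonMask) -> BoundingBox:
    """Tight axis-aligned bounding box over all vertices of all parts."""
    v = mask.all_vertices()
    return BoundingBox(
        float(v[:, 0].min()), float(v[:, 1].min()),
        float(v[:, 0].max()), float(v[:, 1].max()),
    )


def medial_edge_x(mask: PolygonMask, side: Laterality) -> float:
    """x-coordinate of the mask edge facing the nasal septum.

    In a right-cavity image the septum is to the left, so the medial
    boundary of the middle turbinate is its leftmost edge (minimum x);
    in a left-cavity image it is the rightmost edge (maximum x).
    """
    side = Laterality.parse(side)
    xs = mask.all_vertices()[:, 0]
    return float(xs.min()) if side is Laterality.RIGHT else float(xs.max())


def vertical_extent(mask: PolygonMask) -> tuple[float, float, float]:
    """``(y_top, y_bottom, height)`` of the mask: min y, max y, and their difference."""
    ys = mask.all_vertices()[:, 1]
    y_top, y_bottom = float(ys.min()), float(ys.max())
    return y_top, y_bottom, y_bottom - y_top
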