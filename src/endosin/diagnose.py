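"""Conditional IoU logic producing the sinusitis call.

Two overlap rules are evaluated on every frame:

* **MM-Mucus** (primary): IoU between the computed middle-meatus box and
  the mucus box; fires when the IoU strictly exceeds the threshold (0.3).
* **MT-Mucus** (fallback): IoU between the middle-turbinate box and the
  mucus box, covering frames where mucus pools over the MT itself or where
  MM localization fails.

In the default ``permissive`` mode either firing pathway yields a positive
call and all firing pathways are recorded, which reproduces the dual-trigger
accounting where a frame may satisfy both criteria. In ``strict`` mode the
fallback is consulted only when MM localization failed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .geometry import BoundingBox, iou_boxes
from .io import AlgorithmConfig, ClassLabel, EndoscopyFrame, filter_by_confidence
from .localize import MMRegion, best_instance, locate_mm

__all__ = ["DiagnosisResult", "diagnose", "diagnose_batch", "decision_score"]

MM_MUCUS = "MM_mucus"
MT_MUCUS = "MT_mucus"


@dataclass(frozen=True)
class DiagnosisResult:
    """Binary sinusitis call with the pathway evidence behind it."""

    call: str                      # "positive" | "negative"
    triggers: frozenset[str]       # subset of {MM_mucus, MT_mucus}
    iou_mm: float | None           # None when MM localization failed or no mucus
    iou_mt: float | None           # None when no MT or no mucus detected
    mm: MMRegion

    def __post_init__(self) -> None:
        if (self.call == "positive") != bool(self.triggers):
            raise ValueError("a positive call must carry at least one trigger")


def _union_iou(region: BoundingBox, mucus_boxes: Sequence[BoundingBox]) -> float:
    """IoU between a box and the union of all mucus boxes."""
    r = _shapely_box(*region.as_tuple())
    u = unary_union([_shapely_box(*b.as_tuple()) for b in mucus_boxes])
    inter = r.intersection(u).area
    return inter / (r.area + u.area - inter)


def _pathway_iou(
    region: BoundingBox | None,
    mucus_boxes: Sequence[BoundingBox],
    aggregation: str,
) -> float | None:
    if region is None or not mucus_boxes:
        return None
    if aggregation == "union":
        return _union_iou(region, mucus_boxes)
    return max(iou_boxes(region, b) for b in mucus_boxes)


def diagnose(
    frame: EndoscopyFrame, cfg: AlgorithmConfig | None = None
) -> DiagnosisResult:
    """Apply the full rule chain to one confidence-filtered frame.

    Frames that still carry sub-threshold detections are filtered here with
    a warning. Frames without an MT landmark or without mucus always yield a
    negative call with no triggers: absence of evidence is the negative state.
    """
    cfg = cfg or AlgorithmConfig()
    if any(d.confidence < cfg.confidence_threshold for d in frame.detections):
        warnings.warn(
            f"frame {frame.frame_id!r} contains sub-threshold detections; "
            "filtering before diagnosis",
            stacklevel=2,
        )
        frame = filter_by_confidence(frame, cfg)

    mt = best_instance(frame.detections, ClassLabel.MT)
    it = best_instance(frame.detections, ClassLabel.IT)
    mucus_boxes = [d.box for d in frame.by_label(ClassLabel.MUCUS)]

    mm = locate_mm(mt, it, frame.laterality, frame.width, frame.height, cfg)
    iou_mm = _pathway_iou(mm.box, mucus_boxes, cfg.mucus_aggregation)
    iou_mt = _pathway_iou(
        mt.box if mt is not None else None, mucus_boxes, cfg.mucus_aggregation
    )

    mm_fires = iou_mm is not None and iou_mm > cfg.iou_threshold
    mt_fires = iou_mt is not None and iou_mt > cfg.iou_threshold

    if cfg.call_mode == "strict":
        triggers = set()
        if mm_fires:
            triggers.add(MM_MUCUS)
        if mt_fires and not mm.ok:
            triggers.add(MT_MUCUS)
    else:
        triggers = {p for p, fired in ((MM_MUCUS, mm_fires), (MT_MUCUS, mt_fires)) if fired}

    return DiagnosisResult(
        call="positive" if triggers else "negative",
        triggers=frozenset(triggers),
        iou_mm=iou_mm,
        iou_mt=iou_mt,
        mm=mm,
    )


def diagnose_batch(
    frames: Sequence[EndoscopyFrame], cfg: AlgorithmConfig | None = None
) -> list[DiagnosisResult]:
    """Element-wise :func:`diagnose` in input order."""
    cfg = cfg or AlgorithmConfig()
    return [diagnose(frame, cfg) for frame in frames]


def decision_score(result: DiagnosisResult) -> float:
    """Continuous per-frame score for threshold sweeps: the larger pathway IoU.

    Missing pathways contribute 0 (no overlap evidence), so a frame with no
    landmarks or no mucus scores 0 and is never called positive at any
    threshold under the strict-inequality rule.
    """
    return max(result.iou_mm or 0.0, result.iou_mt or 0.0)
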