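"""Seeded generator of endoscopy-like annotation scenes with known ground truth.

The generator emulates the geometry of single-cavity nasal-endoscopy
frames (1024x768 px by default): a vertically elongated middle-turbinate
polygon with its medial face toward the septum, an inferior-turbinate
polygon below it (dropped with probability ``p_it_absent`` to emulate
occlusion, poor image quality or the IT lying outside the frame), and
0-N mucus blobs. Shapes are convex polygons with 8-12 vertices — the
decision rules consume geometry only, so no pixels are rendered.

Ground truth is defined at construction time against the same
middle-meatus rule the pipeline applies:

* ``in_mm`` — the mucus box overlaps the rule-derived MM region with box
  IoU >= 0.5 (frame positive via the primary pathway);
* ``on_mt`` — the mucus pools over the MT box (positive via the fallback
  pathway; this also stands in for frames whose MM is hidden under mucus);
* ``remote`` — mucus placed with a margin of at least twice ``delta_x``
  from both the MM region and the MT box (frame negative).

Scenes are deterministic in ``(seed, index)``. Scenes are built in
right-cavity coordinates and mirrored for left cavities, so a frame forced
to the opposite laterality is the exact mirror image of its twin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import BoundingBox, Laterality, PolygonMask
from .io import AlgorithmConfig, ClassLabel, Detection, EndoscopyFrame
from .localize import locate_mm

__all__ = ["SceneParams", "generate_scene", "generate_suite"]


@dataclass(frozen=True)
class SceneParams:
    """Study-condition knobs of the scene generator.

    Defaults mirror the composition of a tertiary-rhinology test set:
    ~46% right-cavity frames, ~74% sinusitis-positive frames
    (``p_mucus`` x the non-remote placement mass), and a placement mix
    weighted toward mucus pooling on the turbinate, reflecting how often
    the fallback pathway carries the diagnosis in practice.
    """

    width: float = 1024.0
    height: float = 768.0
    laterality_mix: float = 0.46       # fraction of right-cavity frames
    p_it_absent: float = 0.30          # inferior turbinate occluded / out of frame
    p_mucus: float = 0.93              # frame contains any mucus
    placement: str = "mixed"           # {in_mm, on_mt, remote, mixed}
    placement_probs: Mapping[str, float] = field(
        default_factory=lambda: {"in_mm": 0.35, "on_mt": 0.45, "remote": 0.20}
    )
    p_extra_mucus: float = 0.15        # additional remote blob alongside the main one
    jitter_sd: float = 2.0             # per-vertex Gaussian jitter, px
    confidence_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "MT": (0.88, 0.06),
            "IT": (0.82, 0.08),
            "mucus": (0.75, 0.10),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("laterality_mix", "p_it_absent", "p_mucus", "p_extra_mucus"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.placement not in ("in_mm", "on_mt", "remote", "mixed"):
            raise ValueError(f"unknown placement {self.placement!r}")


def _convex_polygon(
    rng: np.random.Generator,
    box: BoundingBox,
    n_vertices: int,
    jitter_sd: float,
) -> PolygonMask:
    """Convex polygon with a tight bounding box equal to ``box`` (before jitter)."""
    # evenly spaced angles with bounded jitter: points on an ellipse in
    # angular order are guaranteed convex and well spread
    step = 2.0 * np.pi / n_vertices
    base = np.arange(n_vertices) * step + rng.uniform(0.0, 2.0 * np.pi)
    angles = np.sort(np.mod(base + rng.uniform(-0.4, 0.4, n_vertices) * step, 2.0 * np.pi))
    x = np.cos(angles)
    y = np.sin(angles)
    # affine map so the extreme vertices touch all four box sides
    x = box.x1 + (x - x.min()) / (x.max() - x.min()) * box.width
    y = box.y1 + (y - y.min()) / (y.max() - y.min()) * box.height
    if jitter_sd > 0:
        x = x + rng.normal(0.0, jitter_sd, n_vertices)
        y = y + rng.normal(0.0, jitter_sd, n_vertices)
        # re-hull so jitter cannot create a self-intersecting ring
        pts = np.column_stack([x, y])
        hull = _convex_hull(pts)
        return PolygonMask.from_vertices(hull)
    return PolygonMask.from_vertices(np.column_stack([x, y]))


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain; counter-clockwise ring without the closing point."""
    pts = sorted(map(tuple, points))
    if len(pts) <= 2:
        raise ValueError("degenerate point set")

    def half(seq):
        out: list = []
        for p in seq:
            while len(out) >= 2 and (
                (out[-1][0] - out[-2][0]) * (p[1] - out[-2][1])
                - (out[-1][1] - out[-2][1]) * (p[0] - out[-2][0])
            ) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(reversed(pts))
    return np.asarray(lower[:-1] + upper[:-1], dtype=float)


def _shrunk(box: BoundingBox, factor: float = 0.9) -> BoundingBox:
    cx, cy = (box.x1 + box.x2) / 2.0, (box.y1 + box.y2) / 2.0
    hw, hh = box.width * factor / 2.0, box.height * factor / 2.0
    return BoundingBox(cx - hw, cy - hh, cx + hw, cy + hh)


def _confidence(rng: np.random.Generator, params: SceneParams, key: str) -> float:
    mean, sd = params.confidence_model[key]
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _generate(
    params: SceneParams,
    index: int,
    laterality: Laterality | None,
    cfg: AlgorithmConfig,
    attempt: int,
) -> tuple[EndoscopyFrame, dict]:
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, index, attempt]))
    sx = params.width / 1024.0
    sy = params.height / 768.0

    if laterality is None:
        side = Laterality.RIGHT if rng.random() < params.laterality_mix else Laterality.LEFT
    else:
        side = Laterality.parse(laterality)

    # canonical right-cavity layout; mirrored at the end for left cavities
    mt_x1 = rng.uniform(430, 470) * sx
    mt_box = BoundingBox(
        mt_x1,
        (y1 := rng.uniform(80, 160) * sy),
        mt_x1 + rng.uniform(150, 190) * sx,
        y1 + rng.uniform(260, 320) * sy,
    )
    it_present = rng.random() >= params.p_it_absent
    detections: list[Detection] = []
    mt_mask = _convex_polygon(rng, mt_box, int(rng.integers(8, 13)), params.jitter_sd)
    mt_det = Detection.from_mask(ClassLabel.MT, _confidence(rng, params, "MT"), mt_mask)
    detections.append(mt_det)

    it_det = None
    if it_present:
        it_x1 = mt_box.x1 - rng.uniform(10, 40) * sx
        it_y1 = mt_box.y2 + rng.uniform(40, 90) * sy
        it_box = BoundingBox(
            it_x1,
            it_y1,
            it_x1 + rng.uniform(200, 260) * sx,
            it_y1 + rng.uniform(120, 180) * sy,
        )
        it_mask = _convex_polygon(rng, it_box, int(rng.integers(8, 13)), params.jitter_sd)
        it_det = Detection.from_mask(
            ClassLabel.IT, _confidence(rng, params, "IT"), it_mask
        )
        detections.append(it_det)

    mm = locate_mm(mt_det, it_det, Laterality.RIGHT, params.width, params.height, cfg)

    has_mucus = rng.random() < params.p_mucus
    if params.placement == "mixed":
        modes = list(params.placement_probs)
        probs = np.asarray([params.placement_probs[m] for m in modes], dtype=float)
        mode = str(rng.choice(modes, p=probs / probs.sum()))
    else:
        mode = params.placement

    def remote_box(upper: bool) -> BoundingBox:
        rx1 = rng.uniform(780, 830) * sx
        ry1 = (rng.uniform(60, 160) if upper else rng.uniform(540, 620)) * sy
        return BoundingBox(
            rx1, ry1, rx1 + rng.uniform(90, 150) * sx, ry1 + rng.uniform(70, 120) * sy
        )

    n_mucus = 0
    if has_mucus:
        if mode == "in_mm":
            if not mm.ok:
                raise _Infeasible("MM localization failed for an in_mm placement")
            target = _shrunk(mm.box)
        elif mode == "on_mt":
            target = _shrunk(mt_det.box)
        else:
            target = remote_box(upper=False)
        mucus_mask = _convex_polygon(
            rng, target, int(rng.integers(8, 13)), params.jitter_sd
        )
        detections.append(
            Detection.from_mask(
                ClassLabel.MUCUS, _confidence(rng, params, "mucus"), mucus_mask
            )
        )
        n_mucus += 1
        if rng.random() < params.p_extra_mucus:
            extra = _convex_polygon(
                rng, remote_box(upper=True), int(rng.integers(8, 13)), params.jitter_sd
            )
            detections.append(
                Detection.from_mask(
                    ClassLabel.MUCUS, _confidence(rng, params, "mucus"), extra
                )
            )
            n_mucus += 1

    gt = "positive" if has_mucus and mode in ("in_mm", "on_mt") else "negative"

    if side is Laterality.LEFT:
        detections = [
            Detection.from_mask(d.label, d.confidence, d.mask.mirrored(params.width))
            for d in detections
        ]

    frame = EndoscopyFrame(
        frame_id=f"scene_{index:05d}",
        width=params.width,
        height=params.height,
        laterality=side,
        detections=tuple(detections),
        gt_label=gt,
    )
    info = {
        "frame_id": frame.frame_id,
        "laterality": side.value,
        "gt_label": gt,
        "placement": mode if has_mucus else None,
        "it_present": it_present,
        "n_mucus": n_mucus,
    }
    return frame, info


class _Infeasible(RuntimeError):
    pass


_MAX_ATTEMPTS = 10


def generate_scene(
    params: SceneParams,
    index: int,
    laterality: Laterality | str | None = None,
    cfg: AlgorithmConfig | None = None,
) -> EndoscopyFrame:
    """One deterministic scene; ``laterality`` forces the side (mirror twin)."""
    cfg = cfg or AlgorithmConfig()
    lat = Laterality.parse(laterality) if laterality is not None else None
    for attempt in range(_MAX_ATTEMPTS):
        try:
            frame, _ = _generate(params, index, lat, cfg, attempt)
            return frame
        except _Infeasible:
            continue
    raise RuntimeError(
        f"could not place scene {index} within {_MAX_ATTEMPTS} attempts; "
        "parameters leave no room for the requested mucus placement"
    )


def generate_suite(
    params: SceneParams,
    n: int,
    cfg: AlgorithmConfig | None = None,
) -> tuple[list[EndoscopyFrame], dict]:
    """Generate ``n`` scenes plus a manifest sufficient to regenerate them."""
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = cfg or AlgorithmConfig()
    frames, records = [], []
    for index in range(n):
        for attempt in range(_MAX_ATTEMPTS):
            try:
                frame, info = _generate(params, index, None, cfg, attempt)
                break
            except _Infeasible:
                continue
        else:
            raise RuntimeError(f"could not place scene {index}")
        frames.append(frame)
        records.append(info)
    manifest = {
        "seed": params.seed,
        "n": n,
        "params": {
            **dataclasses.asdict(params),
            "placement_probs": dict(params.placement_probs),
            "confidence_model": {
                k: list(v) for k, v in params.confidence_model.items()
            },
        },
        "frames": records,
    }
    return frames, manifest
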