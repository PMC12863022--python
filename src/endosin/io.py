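"""Input contract and file I/O for detector outputs and ground-truth annotations.

Detections arrive either as COCO-style annotation JSON (polygon
``segmentation`` lists, one record per instance) or as YOLO segmentation
text files (one file per frame, ``class x1 y1 x2 y2 ...`` with normalized
coordinates). Neither format carries nasal-cavity laterality or the expert
sinusitis label, so both travel in a sidecar metadata CSV keyed by frame id
with columns ``frame_id, laterality, gt_label`` (and optionally
``width, height`` for the YOLO dialect).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .geometry import (
    BoundingBox,
    GeometryError,
    Laterality,
    PolygonMask,
    mask_to_box,
)

if TYPE_CHECKING:  # pragma: no cover
    from .diagnose import DiagnosisResult

__all__ = [
    "ClassLabel",
    "AlgorithmConfig",
    "Detection",
    "EndoscopyFrame",
    "ConfigError",
    "InputError",
    "DEFAULT_CATEGORY_MAP",
    "read_frames",
    "read_metadata",
    "filter_by_confidence",
    "write_results",
    "read_results",
    "write_coco",
    "write_metadata",
]

#: Native acquisition frame size; the rule offsets were calibrated at this scale.
NATIVE_WIDTH = 1024
NATIVE_HEIGHT = 768


class InputError(ValueError):
    """Malformed or inconsistent input files."""


class ConfigError(ValueError):
    """Invalid algorithm configuration."""


class ClassLabel(str, enum.Enum):
    MT = "MT"       # middle turbinate
    IT = "IT"       # inferior turbinate
    MUCUS = "mucus"


#: Default mapping from labeler vocabulary to the three algorithm classes.
DEFAULT_CATEGORY_MAP: dict[str, ClassLabel] = {
    "middle turbinate": ClassLabel.MT,
    "inferior turbinate": ClassLabel.IT,
    "mucus": ClassLabel.MUCUS,
    "mt": ClassLabel.MT,
    "it": ClassLabel.IT,
}

_FALLBACK_Y_RULES = ("extended", "strict_mt")
_CALL_MODES = ("permissive", "strict")
_MUCUS_AGGREGATIONS = ("max", "union")
_MM_DIRECTIONS = ("medial", "lateral")


@dataclass(frozen=True)
class AlgorithmConfig:
    """All rule constants of the decision algorithm.

    Offsets are in pixels at the native 1024x768 resolution and are scaled
    proportionally for other frame sizes. ``delta_x`` and ``delta_y`` set
    the primary middle-meatus box; ``delta_x_safe`` is the conservative
    horizontal margin used when the inferior turbinate is undetected. Both
    the diagnostic IoU comparison and the detection confidence filter use
    strict/inclusive conventions as noted on each field.
    """

    delta_x: float = 50.0        # primary horizontal span, px
    delta_y: float = 20.0        # upward extension above the MT top, px
    delta_x_safe: float = 30.0   # fallback horizontal span, px
    iou_threshold: float = 0.3   # pathway fires when IoU is strictly greater
    confidence_threshold: float = 0.3  # detections kept when confidence >=
    fallback_y_rule: str = "extended"  # {extended, strict_mt}
    call_mode: str = "permissive"      # {permissive, strict}
    mucus_aggregation: str = "max"     # {max, union}
    mm_direction: str = "medial"       # {medial, lateral}

    def __post_init__(self) -> None:
        for name in ("delta_x", "delta_y", "delta_x_safe"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("iou_threshold", "confidence_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name, allowed in (
            ("fallback_y_rule", _FALLBACK_Y_RULES),
            ("call_mode", _CALL_MODES),
            ("mucus_aggregation", _MUCUS_AGGREGATIONS),
            ("mm_direction", _MM_DIRECTIONS),
        ):
            if getattr(self, name) not in allowed:
                raise ConfigError(
                    f"{name} must be one of {allowed}, got {getattr(self, name)!r}"
                )

    def replace(self, **kwargs) -> "AlgorithmConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Detection:
    """One detected instance: class, confidence, box and optional polygon mask."""

    label: ClassLabel
    confidence: float
    box: BoundingBox
    mask: PolygonMask | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise InputError(f"confidence {self.confidence} outside [0, 1]")

    @classmethod
    def from_mask(
        cls, label: ClassLabel, confidence: float, mask: PolygonMask
    ) -> "Detection":
        return cls(label=label, confidence=confidence, box=mask_to_box(mask), mask=mask)

    @property
    def instance_area(self) -> float:
        return self.mask.area if self.mask is not None else self.box.area


@dataclass(frozen=True)
class EndoscopyFrame:
    """One image's detections plus the metadata the rules need."""

    frame_id: str
    width: float
    height: float
    laterality: Laterality
    detections: tuple[Detection, ...] = ()
    gt_label: str | None = None  # "positive" | "negative" | None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InputError("frame dimensions must be positive")
        if self.gt_label is not None and self.gt_label not in ("positive", "negative"):
            raise InputError(f"gt_label must be positive/negative, got {self.gt_label!r}")

    def with_detections(self, detections: Sequence[Detection]) -> "EndoscopyFrame":
        return dataclasses.replace(self, detections=tuple(detections))

    def by_label(self, label: ClassLabel) -> tuple[Detection, ...]:
        return tuple(d for d in self.detections if d.label == label)


# ---------------------------------------------------------------------------
# readers


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sidecar CSV with frame_id, laterality, gt_label (and optional width/height)."""
    df = pd.read_csv(path, dtype={"frame_id": str})
    missing = {"frame_id", "laterality"} - set(df.columns)
    if missing:
        raise InputError(f"metadata file {path} lacks columns {sorted(missing)}")
    if df["frame_id"].duplicated().any():
        dups = df.loc[df["frame_id"].duplicated(), "frame_id"].tolist()
        raise InputError(f"duplicate frame ids in metadata: {dups}")
    return df.set_index("frame_id")


def _gt_from_row(row: pd.Series) -> str | None:
    raw = row.get("gt_label")
    if raw is None or pd.isna(raw) or str(raw).strip().upper() in ("", "NA"):
        return None
    label = str(raw).strip().lower()
    if label not in ("positive", "negative"):
        raise InputError(f"unrecognized gt_label {raw!r}")
    return label


def _normalize_category_map(
    category_map: Mapping[str, ClassLabel | str] | None,
) -> dict[str, ClassLabel]:
    raw = dict(DEFAULT_CATEGORY_MAP) if category_map is None else dict(category_map)
    return {k.strip().lower(): ClassLabel(v) for k, v in raw.items()}


def read_frames(
    path: str | Path,
    format: str,
    metadata: str | Path | pd.DataFrame,
    category_map: Mapping[str, ClassLabel | str] | None = None,
) -> list[EndoscopyFrame]:
    """Read per-frame detections plus sidecar metadata.

    Parameters
    ----------
    path
        COCO annotation JSON file, or a directory of YOLO-seg ``.txt`` files.
    format
        ``"coco_json"`` or ``"yolo_seg"``.
    metadata
        Sidecar CSV path (or pre-read DataFrame indexed by frame_id) carrying
        laterality and the optional expert label. Every frame listed in the
        metadata is returned; frames absent from the annotations get an empty
        detection list. Laterality is required and never guessed.
    category_map
        Mapping from annotation category names to {MT, IT, mucus}.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    if format == "coco_json":
        per_frame = _read_coco(Path(path), _normalize_category_map(category_map), meta)
    elif format == "yolo_seg":
        per_frame = _read_yolo_seg(Path(path), meta)
    else:
        raise InputError(f"unknown annotation format {format!r}")

    frames = []
    for frame_id, row in meta.iterrows():
        lat = Laterality.parse(row["laterality"])
        width = float(row["width"]) if "width" in meta.columns and pd.notna(row.get("width")) else NATIVE_WIDTH
        height = float(row["height"]) if "height" in meta.columns and pd.notna(row.get("height")) else NATIVE_HEIGHT
        dets, dims = per_frame.get(str(frame_id), ((), None))
        if dims is not None:
            width, height = dims
        frames.append(
            EndoscopyFrame(
                frame_id=str(frame_id),
                width=width,
                height=height,
                laterality=lat,
                detections=tuple(dets),
                gt_label=_gt_from_row(row),
            )
        )
    return frames


def _read_coco(
    path: Path, cat_map: dict[str, ClassLabel], meta: pd.DataFrame
) -> dict[str, tuple[tuple[Detection, ...], tuple[float, float] | None]]:
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read COCO JSON {path}: {exc}") from exc

    categories: dict[int, ClassLabel] = {}
    for cat in doc.get("categories", []):
        name = str(cat["name"]).strip().lower()
        if name not in cat_map:
            raise InputError(
                f"unknown category {cat['name']!r}; extend category_map to cover it"
            )
        categories[int(cat["id"])] = cat_map[name]

    images: dict[int, dict] = {int(im["id"]): im for im in doc.get("images", [])}
    dets: dict[str, list[Detection]] = {}
    dims: dict[str, tuple[float, float]] = {}
    for im in images.values():
        fid = str(im.get("file_name", im["id"]))
        dets.setdefault(fid, [])
        if "width" in im and "height" in im:
            dims[fid] = (float(im["width"]), float(im["height"]))

    for ann in doc.get("annotations", []):
        im = images.get(int(ann["image_id"]))
        if im is None:
            raise InputError(f"annotation {ann.get('id')} references unknown image")
        fid = str(im.get("file_name", im["id"]))
        label = categories[int(ann["category_id"])]
        confidence = float(ann.get("score", 1.0))
        seg = ann.get("segmentation")
        if seg:
            parts = [
                list(zip(flat[0::2], flat[1::2]))
                for flat in seg
                if len(flat) >= 6
            ]
            if not parts:
                raise InputError(f"annotation {ann.get('id')} has a degenerate polygon")
            mask = PolygonMask.from_parts(parts)
            det = Detection.from_mask(label, confidence, mask)
        else:
            x, y, w, h = ann["bbox"]
            det = Detection(label, confidence, BoundingBox(x, y, x + w, y + h))
        dets.setdefault(fid, []).append(det)
    return {fid: (tuple(v), dims.get(fid)) for fid, v in dets.items()}


_YOLO_CLASS_ORDER = (ClassLabel.MT, ClassLabel.IT, ClassLabel.MUCUS)


def _read_yolo_seg(
    path: Path, meta: pd.DataFrame
) -> dict[str, tuple[tuple[Detection, ...], tuple[float, float] | None]]:
    if not path.is_dir():
        raise InputError(f"YOLO-seg input must be a directory of .txt files: {path}")
    out: dict[str, tuple[tuple[Detection, ...], tuple[float, float] | None]] = {}
    for txt in sorted(path.glob("*.txt")):
        fid = txt.stem
        if fid not in meta.index:
            raise InputError(f"frame {fid!r} missing from metadata (laterality unknown)")
        row = meta.loc[fid]
        width = float(row["width"]) if "width" in meta.columns and pd.notna(row.get("width")) else NATIVE_WIDTH
        height = float(row["height"]) if "height" in meta.columns and pd.notna(row.get("height")) else NATIVE_HEIGHT
        dets = []
        for lineno, line in enumerate(txt.read_text().splitlines(), 1):
            tokens = line.split()
            if not tokens:
                continue
            cls_idx = int(tokens[0])
            if cls_idx >= len(_YOLO_CLASS_ORDER):
                raise InputError(f"{txt}:{lineno}: unknown class index {cls_idx}")
            rest = [float(t) for t in tokens[1:]]
            # an odd coordinate count means a trailing confidence value
            if len(rest) % 2 == 1:
                confidence, coords = rest[-1], rest[:-1]
            else:
                confidence, coords = 1.0, rest
            if len(coords) < 6:
                raise InputError(f"{txt}:{lineno}: polygon needs at least 3 vertices")
            verts = [
                (coords[i] * width, coords[i + 1] * height)
                for i in range(0, len(coords), 2)
            ]
            dets.append(
                Detection.from_mask(
                    _YOLO_CLASS_ORDER[cls_idx], confidence, PolygonMask.from_vertices(verts)
                )
            )
        out[fid] = (tuple(dets), (width, height))
    return out


# ---------------------------------------------------------------------------
# confidence filter


def filter_by_confidence(
    frame: EndoscopyFrame, cfg: AlgorithmConfig
) -> EndoscopyFrame:
    """Keep detections with confidence >= the configured threshold (order preserved)."""
    kept = tuple(
        d for d in frame.detections if d.confidence >= cfg.confidence_threshold
    )
    return frame.with_detections(kept)


# ---------------------------------------------------------------------------
# writers


def write_results(
    frames: Sequence[EndoscopyFrame],
    results: Sequence["DiagnosisResult"],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write per-frame calls to ``results.csv`` plus a ``summary.json`` run summary."""
    if len(frames) != len(results):
        raise InputError(
            f"{len(frames)} frames but {len(results)} results; one result per frame required"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame, res in zip(frames, results):
        mm_box = res.mm.box.as_tuple() if res.mm.box is not None else (None,) * 4
        rows.append(
            {
                "frame_id": frame.frame_id,
                "laterality": frame.laterality.value,
                "gt_label": frame.gt_label,
                "call": res.call,
                "triggers": ";".join(sorted(res.triggers)),
                "iou_mm": res.iou_mm,
                "iou_mt": res.iou_mt,
                "mm_method": res.mm.method,
                "mm_clamped": res.mm.clamped,
                "mm_x1": mm_box[0],
                "mm_y1": mm_box[1],
                "mm_x2": mm_box[2],
                "mm_y2": mm_box[3],
            }
        )
    columns = [
        "frame_id", "laterality", "gt_label", "call", "triggers",
        "iou_mm", "iou_mt", "mm_method", "mm_clamped",
        "mm_x1", "mm_y1", "mm_x2", "mm_y2",
    ]
    table = pd.DataFrame(rows, columns=columns)
    csv_path = out_dir / "results.csv"
    table.to_csv(csv_path, index=False)

    summary = {
        "n_frames": len(frames),
        "n_positive_calls": int(sum(r.call == "positive" for r in results)),
        "n_negative_calls": int(sum(r.call == "negative" for r in results)),
        "trigger_counts": {
            "MM_mucus": int(sum("MM_mucus" in r.triggers for r in results)),
            "MT_mucus": int(sum("MT_mucus" in r.triggers for r in results)),
        },
        "mm_method_counts": {
            m: int(sum(r.mm.method == m for r in results))
            for m in ("primary", "fallback", "failed")
        },
    }
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def read_results(csv_path: str | Path) -> pd.DataFrame:
    """Read back a ``results.csv`` written by :func:`write_results`."""
    return pd.read_csv(csv_path, dtype={"frame_id": str}, keep_default_na=True)


def write_coco(
    frames: Sequence[EndoscopyFrame], ann_path: str | Path
) -> Path:
    """Write frames as COCO-style annotation JSON (detections with scores)."""
    cat_ids = {ClassLabel.MT: 1, ClassLabel.IT: 2, ClassLabel.MUCUS: 3}
    cat_names = {
        ClassLabel.MT: "middle turbinate",
        ClassLabel.IT: "inferior turbinate",
        ClassLabel.MUCUS: "mucus",
    }
    images, annotations = [], []
    ann_id = 1
    for img_id, frame in enumerate(frames, start=1):
        images.append(
            {
                "id": img_id,
                "file_name": frame.frame_id,
                "width": frame.width,
                "height": frame.height,
            }
        )
        for det in frame.detections:
            record: dict = {
                "id": ann_id,
                "image_id": img_id,
                "category_id": cat_ids[det.label],
                "score": det.confidence,
                "bbox": [
                    det.box.x1,
                    det.box.y1,
                    det.box.width,
                    det.box.height,
                ],
                "area": det.instance_area,
                "iscrowd": 0,
            }
            if det.mask is not None:
                record["segmentation"] = [
                    [coord for xy in part for coord in xy] for part in det.mask.parts
                ]
            annotations.append(record)
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": cid, "name": cat_names[label]} for label, cid in cat_ids.items()
        ],
    }
    ann_path = Path(ann_path)
    ann_path.parent.mkdir(parents=True, exist_ok=True)
    ann_path.write_text(json.dumps(doc) + "\n")
    return ann_path


def write_metadata(frames: Sequence[EndoscopyFrame], path: str | Path) -> Path:
    """Write the sidecar metadata CSV for a set of frames."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame_id": [f.frame_id for f in frames],
            "laterality": [f.laterality.value for f in frames],
            "gt_label": [f.gt_label if f.gt_label is not None else "NA" for f in frames],
            "width": [f.width for f in frames],
            "height": [f.height for f in frames],
        }
    ).to_csv(path, index=False)
    return path
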