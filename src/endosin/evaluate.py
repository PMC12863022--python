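"""Evaluation stack: classification metrics, segmentation matching, ROC,
trigger-pathway accounting and annotation-agreement statistics.

Percentages follow the clinical-reporting convention of one decimal with
half-up rounding (see :func:`round_pct`); all functions return unrounded
floats and leave rounding to the report layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

from .diagnose import MM_MUCUS, MT_MUCUS, DiagnosisResult, decision_score
from .geometry import iou_boxes
from .io import ClassLabel, EndoscopyFrame, InputError

__all__ = [
    "ConfusionCounts",
    "ClassSegMetrics",
    "RocCurve",
    "TriggerTally",
    "classification_metrics",
    "f1_from_pr",
    "segmentation_metrics",
    "roc_analysis",
    "pathway_stats",
    "agreement",
    "round_pct",
]


def round_pct(value: float | None, ndigits: int = 1) -> float | None:
    """Half-up rounding as used in clinical tables (79.25 -> 79.3)."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(num: float, den: float) -> float | None:
    return 100.0 * num / den if den > 0 else None


def f1_from_pr(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall, both on the percent scale."""
    if precision + recall <= 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls, calls: Sequence[str], gt_labels: Sequence[str]
    ) -> "ConfusionCounts":
        if len(calls) != len(gt_labels):
            raise InputError("calls and ground-truth labels differ in length")
        tp = fp = tn = fn = 0
        for call, gt in zip(calls, gt_labels):
            if gt not in ("positive", "negative"):
                raise InputError(f"missing or invalid ground-truth label {gt!r}")
            if call == "positive":
                tp += gt == "positive"
                fp += gt == "negative"
            else:
                tn += gt == "negative"
                fn += gt == "positive"
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


def classification_metrics(
    calls: Sequence[str] | Sequence[DiagnosisResult],
    gt_labels: Sequence[str],
) -> dict:
    """Sensitivity, specificity, precision, accuracy and F1 (percent) plus counts.

    Ratios with a zero denominator are reported as ``None`` rather than
    silently coerced to 0.
    """
    call_strs = [c.call if isinstance(c, DiagnosisResult) else c for c in calls]
    counts = ConfusionCounts.from_labels(call_strs, gt_labels)
    sens = _pct(counts.tp, counts.tp + counts.fn)
    spec = _pct(counts.tn, counts.tn + counts.fp)
    prec = _pct(counts.tp, counts.tp + counts.fp)
    acc = _pct(counts.tp + counts.tn, counts.n)
    f1 = f1_from_pr(prec, sens) if prec is not None and sens is not None else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f1": f1,
        "counts": counts,
    }


# ---------------------------------------------------------------------------
# segmentation matching


@dataclass(frozen=True)
class ClassSegMetrics:
    label: ClassLabel
    mean_iou: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    n_gt: int
    n_pred: int
    tp: int
    fp: int
    fn: int


def _instance_polygon(det) -> Polygon:
    if det.mask is not None:
        return unary_union([Polygon(part) for part in det.mask.parts]).buffer(0)
    x1, y1, x2, y2 = det.box.as_tuple()
    return Polygon([(x1, y1), (x2, y1), (x2, y2), (x1, y2)])


def _instance_iou(a, b) -> float:
    if a.mask is None and b.mask is None:
        return iou_boxes(a.box, b.box)
    pa, pb = _instance_polygon(a), _instance_polygon(b)
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    return inter / union if union > 0 else 0.0


def segmentation_metrics(
    pred_frames: Sequence[EndoscopyFrame],
    gt_frames: Sequence[EndoscopyFrame],
    match_iou: float = 0.5,
) -> list[ClassSegMetrics]:
    """Per-class detection/segmentation quality via greedy confidence matching.

    Within each frame and class, predictions are taken in descending
    confidence and matched to the unused same-class ground-truth instance of
    highest mask IoU; a match requires IoU >= ``match_iou``. Matched pairs
    are true positives, unmatched predictions false positives, unmatched
    ground truth false negatives; mean IoU is over matched pairs.
    """
    gt_by_id = {f.frame_id: f for f in gt_frames}
    if len(gt_by_id) != len(gt_frames):
        raise InputError("duplicate frame ids in ground-truth frames")
    stats: dict[ClassLabel, dict] = {
        label: {"tp": 0, "fp": 0, "fn": 0, "ious": [], "n_gt": 0, "n_pred": 0}
        for label in ClassLabel
    }
    for pred in pred_frames:
        if pred.frame_id not in gt_by_id:
            raise InputError(f"prediction frame {pred.frame_id!r} has no ground truth")
        gt = gt_by_id[pred.frame_id]
        for label in ClassLabel:
            preds = sorted(
                pred.by_label(label), key=lambda d: d.confidence, reverse=True
            )
            gts = list(gt.by_label(label))
            s = stats[label]
            s["n_gt"] += len(gts)
            s["n_pred"] += len(preds)
            unused = set(range(len(gts)))
            for p in preds:
                best_j, best_iou = None, match_iou
                for j in unused:
                    iou = _instance_iou(p, gts[j])
                    if iou >= best_iou:
                        best_j, best_iou = j, iou
                if best_j is None:
                    s["fp"] += 1
                else:
                    unused.discard(best_j)
                    s["tp"] += 1
                    s["ious"].append(best_iou)
            s["fn"] += len(unused)

    out = []
    for label in ClassLabel:
        s = stats[label]
        prec = _pct(s["tp"], s["tp"] + s["fp"])
        rec = _pct(s["tp"], s["tp"] + s["fn"])
        f1 = f1_from_pr(prec, rec) if prec is not None and rec is not None else None
        out.append(
            ClassSegMetrics(
                label=label,
                mean_iou=float(np.mean(s["ious"])) if s["ious"] else None,
                precision=prec,
                recall=rec,
                f1=f1,
                n_gt=s["n_gt"],
                n_pred=s["n_pred"],
                tp=s["tp"],
                fp=s["fp"],
                fn=s["fn"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# ROC / threshold sensitivity


@dataclass(frozen=True)
class RocCurve:
    thresholds: tuple[float, ...]  # descending
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    auc: float
    ci_low: float | None
    ci_high: float | None


def _binary_gt(gt_labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([g == "positive" for g in gt_labels], dtype=bool)
    for g in gt_labels:
        if g not in ("positive", "negative"):
            raise InputError(f"invalid ground-truth label {g!r}")
    return y


def _curve(scores: np.ndarray, y: np.ndarray, thresholds: np.ndarray):
    pos, neg = int(y.sum()), int((~y).sum())
    tpr = [(scores[y] > t).sum() / pos for t in thresholds]
    fpr = [(scores[~y] > t).sum() / neg for t in thresholds]
    return np.asarray(tpr), np.asarray(fpr)


def _auc_trapezoid(tpr: np.ndarray, fpr: np.ndarray) -> float:
    # anchor at (0,0) and (1,1) so the curve spans the full unit square
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    order = np.argsort(f, kind="stable")
    return float(np.trapezoid(t[order], f[order]))


def roc_analysis(
    results: Sequence[DiagnosisResult] | Sequence[float],
    gt_labels: Sequence[str],
    thresholds: Sequence[float] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocCurve:
    """Threshold-sensitivity (ROC) analysis of the IoU decision statistic.

    The per-frame score is the larger of the two pathway IoUs; a frame is
    called positive at threshold t when its score strictly exceeds t,
    matching the diagnostic rule. By default every distinct observed score
    serves as a threshold ("all possible thresholds"), which makes the
    trapezoidal AUC identical to the concordance-pair (Mann-Whitney)
    estimator with ties counted one half. The 95% CI is a seeded
    nonparametric percentile bootstrap over frames.
    """
    scores = np.asarray(
        [decision_score(r) if isinstance(r, DiagnosisResult) else float(r) for r in results]
    )
    y = _binary_gt(gt_labels)
    if len(scores) != len(y):
        raise InputError("scores and ground-truth labels differ in length")
    if y.all() or not y.any():
        raise InputError("ROC analysis requires both classes in the ground truth")

    if thresholds is None:
        grid = np.unique(scores)[::-1]
    else:
        grid = np.asarray(sorted(thresholds, reverse=True), dtype=float)
    tpr, fpr = _curve(scores, y, grid)
    auc = _auc_trapezoid(tpr, fpr)

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(scores)
        boot = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.all() or not yb.any():
                continue  # degenerate resample carries no AUC information
            sb = scores[idx]
            gb = np.unique(sb)[::-1]
            tb, fb = _curve(sb, yb, gb)
            boot.append(_auc_trapezoid(tb, fb))
        if boot:
            ci_low, ci_high = (
                float(np.percentile(boot, 2.5)),
                float(np.percentile(boot, 97.5)),
            )
    return RocCurve(
        thresholds=tuple(grid.tolist()),
        tpr=tuple(tpr.tolist()),
        fpr=tuple(fpr.tolist()),
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
    )


# ---------------------------------------------------------------------------
# trigger-pathway accounting


_PATHWAYS = (MM_MUCUS, MT_MUCUS)


@dataclass(frozen=True)
class TriggerTally:
    """Pathway firing counts per (laterality, ground-truth) stratum."""

    counts: Mapping[tuple[str, str], Mapping[str, int]]

    @classmethod
    def from_results(
        cls,
        frames: Sequence[EndoscopyFrame],
        results: Sequence[DiagnosisResult],
    ) -> "TriggerTally":
        if len(frames) != len(results):
            raise InputError("frames and results differ in length")
        counts: dict[tuple[str, str], dict[str, int]] = {}
        for frame, res in zip(frames, results):
            if frame.gt_label is None:
                raise InputError(f"frame {frame.frame_id!r} lacks a ground-truth label")
            key = (frame.laterality.value, frame.gt_label)
            row = counts.setdefault(key, {p: 0 for p in _PATHWAYS})
            for pathway in res.triggers:
                row[pathway] += 1
        return cls(counts=counts)

    @classmethod
    def from_counts(
        cls, table: Mapping[tuple[str, str], tuple[int, int]]
    ) -> "TriggerTally":
        """Build from ``{(laterality, gt): (mm_count, mt_count)}``."""
        return cls(
            counts={
                key: {MM_MUCUS: int(mm), MT_MUCUS: int(mt)}
                for key, (mm, mt) in table.items()
            }
        )

    def total(self, pathway: str, gt: str | None = None) -> int:
        return sum(
            row[pathway]
            for (lat, g), row in self.counts.items()
            if gt is None or g == gt
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"laterality": lat, "gt_label": g, **row}
            for (lat, g), row in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["laterality", "gt_label", *_PATHWAYS])


def pathway_stats(tally: TriggerTally) -> dict:
    """Pathway precision, false-positive share and usage share (percent).

    Pathway precision is the fraction of a pathway's firings that occurred
    in ground-truth-positive strata; fp_share is a pathway's share of all
    firings in ground-truth-negative strata; usage_share is its share of
    total firings.
    """
    grand = sum(tally.total(p) for p in _PATHWAYS)
    neg_total = sum(tally.total(p, gt="negative") for p in _PATHWAYS)
    out: dict[str, dict] = {}
    for p in _PATHWAYS:
        fired = tally.total(p)
        out[p] = {
            "precision": _pct(tally.total(p, gt="positive"), fired),
            "fp_share": _pct(tally.total(p, gt="negative"), neg_total),
            "usage_share": _pct(fired, grand),
        }
    return out


# ---------------------------------------------------------------------------
# inter-rater agreement


def _binary_f1(a: np.ndarray, b: np.ndarray) -> float | None:
    """F1 of rater ``a`` against reference ``b`` on presence labels."""
    tp = int(((a == 1) & (b == 1)).sum())
    fp = int(((a == 1) & (b == 0)).sum())
    fn = int(((a == 0) & (b == 1)).sum())
    if 2 * tp + fp + fn == 0:
        return None
    return 2 * tp / (2 * tp + fp + fn)


def agreement(
    ratings: Sequence[Sequence[int]] | np.ndarray,
    reference: int = 0,
) -> dict:
    """Agreement between raters assigning class-presence labels to items.

    Parameters
    ----------
    ratings
        Items x raters array of categorical labels (binary 0/1 for the
        presence F1; any fixed category set for Fleiss kappa). Missing
        values are not allowed — every rater labels every item.
    reference
        Column index of the reference rater (the expert) against which the
        per-rater F1 scores are computed.

    Returns ``pairwise_f1_mean``, ``pairwise_f1_sd`` (over the non-reference
    raters) and ``fleiss_kappa``.
    """
    arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InputError("ratings must be items x raters with at least two raters")
    if arr.shape[0] < 1:
        raise InputError("at least one item is required")
    if pd.isna(arr).any():
        raise InputError("missing ratings are not allowed")
    arr = arr.astype(int)

    ref = arr[:, reference]
    f1s = [
        f
        for j in range(arr.shape[1])
        if j != reference
        for f in [_binary_f1(arr[:, j], ref)]
        if f is not None
    ]
    table, _ = aggregate_raters(arr)
    kappa = float(fleiss_kappa(table))
    return {
        "pairwise_f1_mean": float(np.mean(f1s)) if f1s else None,
        "pairwise_f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else None,
        "fleiss_kappa": kappa,
    }
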