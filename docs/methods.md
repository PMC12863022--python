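# Methods

## Problem and model

`endosin` implements a rule-based decision algorithm for screening chronic
sinusitis (CRSsNP) on single frames of nasal endoscopy. Its input is the
output of an upstream multi-class instance detector — middle turbinate
(MT), inferior turbinate (IT) and mucus, each with a confidence score, a
bounding box and usually a polygon mask. The package does not train or run
a detector; the detector is a pluggable input contract (COCO-style JSON or
YOLO-seg text), filtered at a confidence of 0.3 (inclusive: ties are kept).

The middle meatus (MM) — the drainage channel where purulent mucus
indicates active inflammation — is often not directly visible, so its
region is inferred geometrically from the landmarks:

1. **Medial boundary.** For a right cavity the medial MT boundary is the
   leftmost mask edge (minimum x); for a left cavity the rightmost
   (maximum x). Laterality is required metadata and never inferred from
   pixels. Edges are read off polygon vertices, not rasterized contours,
   so localization is deterministic and resolution-independent;
   rasterization appears only as a test oracle.
2. **Primary MM box (MT + IT detected).** With medial edge `e`,
   `y1 = max(y_MTtop − Δy, 0)`, `y2 = y_ITtop`, and a horizontal span of
   `Δx` from `e` toward the septum (decreasing x in a right cavity,
   mirrored for the left). Defaults: `Δx = 50 px`, `Δy = 20 px` at the
   native 1024×768 resolution.
3. **Fallback MM box (IT undetected — occlusion, poor image quality, IT
   out of frame).** The vertical rule extends below the MT:
   `y2 = y_MTbottom + 0.5·h_MT`; the horizontal span shrinks to the
   conservative `Δx_safe = 30 px`. A stricter variant that bounds the
   region by the MT extent alone is available via
   `fallback_y_rule = "strict_mt"`. We default to the extended rule because
   it is the more specific of the two printed conventions for the
   IT-undetected case.
4. **Diagnosis.** Two overlap statistics are computed on bounding boxes:
   IoU(MM box, mucus box) and IoU(MT box, mucus box). A pathway fires when
   its IoU *strictly* exceeds 0.3. In the default `permissive` mode either
   pathway yields a positive call and all firing pathways are recorded
   (frames may satisfy both criteria — this is what makes the pathway-usage
   accounting add up); in `strict` mode the MT–mucus fallback is consulted
   only when MM localization fails. With several mucus instances the
   maximum single-instance IoU is used (`mucus_aggregation = "union"`
   computes IoU against the union of mucus boxes instead). Frames without
   an MT or without mucus are negative: no landmark evidence, no call.

Degenerate situations never crash: zero offsets, boxes clipped away at the
frame border, or an IT top above the region's upper bound all yield a
`failed` MM region, which simply disables the primary pathway.

### Direction of the horizontal span

Anatomically the MM lies lateral to the MT, yet the one fully written-out
construction (the fallback) extends the region from the medial MT edge
toward the septum. We follow that construction by default — it is the only
one spelled out, and the laterality symmetry follows the medial-boundary
rule — and expose `mm_direction = "lateral"` for users who prefer the
anatomical reading. Published figures would disambiguate; the text alone
does not.

### Offset scaling

The offsets were calibrated at 1024×768. For other frame sizes they scale
proportionally (`Δx`, `Δx_safe` by width/1024; `Δy` by height/768), so the
construction is invariant under uniform resampling of a frame.

## Evaluation stack

* **Classification metrics** per laterality stratum: sensitivity,
  specificity, precision, accuracy and F1 = 2PR/(P+R), reported in percent.
  Zero-denominator ratios are returned as `None`, never silently 0.
  Table percentages use one-decimal half-up rounding.
* **Segmentation metrics**: per class, predictions are matched greedily in
  descending confidence to unused same-class ground-truth instances at mask
  IoU ≥ 0.5 (the COCO-style convention); TP/FP/FN counts give P/R/F1, and
  mean IoU is over matched pairs.
* **Threshold sensitivity (ROC)**: the per-frame score is the larger of
  the two pathway IoUs, with absent pathways contributing 0; a frame is
  positive at threshold t when its score strictly exceeds t, matching the
  diagnostic rule. The default grid is every distinct observed score
  ("all possible thresholds"), which makes the trapezoidal AUC — anchored
  at (0,0) and (1,1) — exactly the concordance-pair (Mann–Whitney)
  estimator with ties counted one half. The 95% CI is a seeded percentile
  bootstrap over frames (2,000 resamples; degenerate single-class
  resamples are skipped).
* **Pathway accounting**: firings tallied per (laterality × ground truth)
  stratum. Pathway precision = firings in positive strata / all firings of
  that pathway; fp-share = a pathway's share of all firings in negative
  strata; usage-share = its share of all firings.
* **Agreement**: mean (± sd) per-rater-vs-reference binary F1 and Fleiss
  κ (via `statsmodels`) for multi-rater annotation quality control.

## Synthetic scenes

The generator emulates single-cavity 1024×768 annotation scenes as pure
geometry — convex 8–12-vertex polygons with optional Gaussian vertex
jitter — because the decision rules consume geometry only. A vertically
elongated MT sits mid-frame with its medial face toward the septum; an IT
lies below it and is dropped with probability `p_it_absent` (emulating
occlusion or the IT being out of frame); mucus blobs are placed by mode:

* `in_mm`: the mucus box overlaps the rule-derived MM region with box
  IoU ≥ 0.5 → ground-truth positive via the primary pathway;
* `on_mt`: mucus pools over the MT box (IoU ≈ 0.8) → positive via the
  fallback pathway; this also stands in for frames whose MM is hidden
  under mucus;
* `remote`: mucus placed with a margin of at least 2·Δx from both the MM
  region and the MT box → negative, with no borderline IoUs.

Ground truth is defined at construction time against the same MM rule the
pipeline applies, which is deliberate: the recovery suite checks that the
decision chain reproduces its own construction, i.e. that plumbing,
laterality mirroring, clamping and threshold logic introduce no errors.
It does **not** validate the clinical rule against real anatomy; passing
tests say nothing about detector quality, purulent-vs-serous mucus
appearance, lighting, or anatomical variants (septal deviation, spurs)
that drive the real error modes. Scenes are built in right-cavity
coordinates and mirrored for left cavities, so forcing the opposite
laterality yields an exact mirror twin.

Defaults are chosen to resemble the composition of a tertiary-rhinology
test cohort: ~74% positive frames (`p_mucus = 0.93` with 20% of placements
remote), 46% right-cavity frames, a placement mix weighted toward on-MT
deposits (the fallback pathway carries roughly two-thirds of usage in such
material), `p_it_absent = 0.30` (no published rate; a realistic occlusion
frequency), and `jitter_sd = 2 px` of annotation noise. Scenes are
deterministic in `(seed, index)`; a per-scene retry bound (10 attempts)
guards infeasible placements and has never been observed to trigger at the
default geometry.

## Numerical choices

* Boxes are closed real intervals; IoU is exact interval arithmetic, with
  degenerate (zero-area) boxes rejected at construction.
* Polygon validity requires ≥ 3 vertices, non-zero shoelace area and
  non-zero extent on both axes (the extent check guards float-noise areas
  of collinear rings).
* Multi-part masks take min/max over all parts for boxes and edges — a
  conservative tight cover of fragmented instances.
* Among multiple same-class instances the highest-confidence one is used;
  ties break by larger mask area, then first occurrence.
* Confidence filtering is inclusive (≥ 0.3); the diagnostic IoU comparison
  is strict (> 0.3). A frame whose pathway IoU is exactly 0.3 is negative.

## Problem sizes

The test and acceptance suites run the recovery analysis on 200 scenes,
oracle-equivalence checks on 1,000 random box pairs / label vectors, and
the threshold-monotonicity scan on a 101-point grid — sizes at which every
check is exact or tightly bounded while the whole suite stays fast.

## Known limitations

* Stage-3 IoU is computed on bounding boxes, as the diagnostic formulas
  are written; mask-level IoU for the diagnosis is intentionally out of
  scope (boxes of concave mucus shapes can overestimate overlap).
* No purulent/serous mucus discrimination, polyp handling, video context,
  or depth-aware localization.
* Whether published results used permissive or strict pathway gating is
  not determinable from the text; both are implemented, permissive being
  the default because dual-trigger accounting requires it.
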