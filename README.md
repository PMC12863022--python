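# endosin

Rule-based sinusitis assessment from multi-class nasal-endoscopy
detections.

`endosin` is for researchers and engineers building computer-assisted
screening for chronic rhinosinusitis without nasal polyps (CRSsNP) from
single nasal-endoscopy frames. An upstream instance detector supplies
per-frame detections of three classes — middle turbinate (MT), inferior
turbinate (IT) and mucus — and this package supplies everything after
that: geometric localization of the middle meatus (MM), the
IoU-threshold diagnostic rule, the full evaluation stack, and a seeded
synthetic-scene generator so the whole chain is testable without
clinical images.

## The algorithm

The MM — the drainage channel where purulent mucus signals active sinus
inflammation — is frequently not directly visible, so its region is
constructed from the landmarks. With the medial MT edge
`x_MTedge` (leftmost mask edge in a right cavity, rightmost in a left
cavity):

* **primary** (MT + IT detected):
  `y1 = max(y_MTtop − Δy, 0)`, `y2 = y_ITtop`, horizontal span `Δx`
  from `x_MTedge` toward the septum, with `Δx = 50 px`, `Δy = 20 px`
  at 1024×768;
* **fallback** (IT undetected):
  `y2 = y_MTbottom + 0.5·h_MT`, span `Δx_safe = 30 px`.

Diagnosis is conditional on box overlap: the frame is called positive
when `IoU(MM, mucus) > 0.3` (primary pathway) or `IoU(MT, mucus) > 0.3`
(fallback pathway, for mucus pooling over the turbinate or frames where
MM localization fails). Both pathways are evaluated and recorded per
frame; which one fired is part of the output, since the two pathways
have measurably different precision.

See `docs/methods.md` for the full construction, the evaluation
conventions, and what the synthetic scenes do and do not emulate.

## Worked example

```python
from endosin import (SceneParams, generate_suite, diagnose_batch,
                     classification_metrics)

params = SceneParams(seed=42, jitter_sd=0.0)   # noiseless scenes
frames, _ = generate_suite(params, 5)
results = diagnose_batch(frames)
for f, r in zip(frames, results):
    print(f"{f.frame_id}  {f.laterality.value:>5}  gt={f.gt_label:<8} "
          f"call={r.call:<8} triggers={sorted(r.triggers)} "
          f"iou_mm={round(r.iou_mm, 3)} iou_mt={round(r.iou_mt, 3)} "
          f"mm={r.mm.method}")
m = classification_metrics(results, [f.gt_label for f in frames])
print("sensitivity:", m["sensitivity"], "specificity:", m["specificity"])
```

prints

```text
scene_00000   left  gt=positive call=positive triggers=['MM_mucus'] iou_mm=0.81 iou_mt=0.0 mm=primary
scene_00001   left  gt=negative call=negative triggers=[] iou_mm=0.0 iou_mt=0.0 mm=primary
scene_00002  right  gt=positive call=positive triggers=['MM_mucus'] iou_mm=0.81 iou_mt=0.0 mm=primary
scene_00003  right  gt=positive call=positive triggers=['MT_mucus'] iou_mm=0.0 iou_mt=0.81 mm=primary
scene_00004   left  gt=positive call=positive triggers=['MM_mucus'] iou_mm=0.81 iou_mt=0.0 mm=primary
sensitivity: 100.0 specificity: 100.0
```

Each row is one frame: the construction-time ground truth (`gt`), the
algorithm's call, which overlap pathway fired, the two pathway IoU
values, and how the MM box was built (`primary` = MT+IT, `fallback` =
MT only). Scene 3 is a frame whose mucus pools over the turbinate
itself: the MM pathway sees no overlap and the MT–mucus fallback carries
the diagnosis. On noiseless scenes the rule chain reproduces the
construction ground truth exactly — hence 100% sensitivity and
specificity.

The same pipeline runs from the shell:

```sh
endosin simulate --n 200 --seed 7 --jitter-sd 0 --out scenes/
endosin diagnose --annotations scenes/annotations.json --metadata scenes/metadata.csv --out calls/
endosin evaluate --annotations scenes/annotations.json --metadata scenes/metadata.csv --out report/
```

`evaluate` writes `report.json` (overall and per-laterality
classification metrics, trigger-pathway tallies and pathway precision,
AUC with bootstrap CI) plus `roc_points.csv` and the per-frame
`results.csv`.

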