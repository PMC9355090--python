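# seedlingscreen

Selective screening of plug-tray seedlings from side-view images, for
greenhouse transplanting rigs and phenotyping pipelines. During automated
transplantation each seedling passes a camera; `seedlingscreen` decides per
station whether the plant is **healthy**, **unhealthy** or **absent**, so
that only healthy seedlings enter the cultivation trough and every culled
position is logged for replanting.

Two classifiers are provided over a shared HSV color-threshold extraction
front end:

- a **rule-based screen**: leaf pixels (yellow ∪ green HSV ranges) and
  substrate pixels (black range) are masked, denoised by morphological
  closing + Gaussian re-thresholding, and counted; a seedling is healthy iff
  leaf area ≥ 2,300 px and substrate area ≥ 1,300 px, absent iff both areas
  are zero, unhealthy otherwise;
- a **learned screen**: a 3-class residual network (an 18-layer transfer
  backbone with its head replaced by a 3-way fully connected layer —
  11,178,051 trainable parameters — or a compact 16→256-channel variant)
  trained with cross-entropy/Adam on white-background extracted crops
  resized to 224×224.

Evaluation follows the standard multiclass conventions: a predicted×true
confusion matrix, per-class TP/FP/FN/TN, precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), accuracy = trace/total.

A synthetic frame generator (gray background, dark substrate plug, green
leaf blobs, with exact ground-truth areas and labels) makes the whole
pipeline testable without any image download; see `docs/methods.md` for the
model details and for what the synthetic data does and does not emulate.

## Worked example

Generate a labelled synthetic dataset, screen one image, and evaluate the
published 900-seedling validation matrix:

```
$ seedlingscreen synth --n 2 --seed 3 --out data
wrote 6 images to data

$ seedlingscreen screen-physical --in data/healthy_0000.png
{"label": "healthy", "leaf_area": 2989, "substrate_area": 1828}
```

The screen measured 2,989 leaf pixels (≥ 2,300) and 1,828 substrate pixels
(≥ 1,300), so the seedling passes. In the library, the network screen's
validation confusion matrix (rows = predicted, columns = true, order
healthy/unhealthy/none) evaluates to:

```python
>>> from seedlingscreen.evaluation import report, LABELS
>>> cm = [[439, 11, 0], [12, 138, 0], [0, 0, 300]]
>>> true = [LABELS[t] for p in range(3) for t in range(3) for _ in range(cm[p][t])]
>>> pred = [LABELS[p] for p in range(3) for t in range(3) for _ in range(cm[p][t])]
>>> rep = report(true, pred)
>>> rep["accuracy_pct"], rep["misclassified"]
('97.44%', 23)
>>> [(c, rep["per_class"][c]["precision_pct"], rep["per_class"][c]["recall_pct"],
...   rep["per_class"][c]["f1_pct"]) for c in LABELS]
[('healthy', '97.56%', '97.34%', '97.45%'),
 ('unhealthy', '92%', '92.62%', '92.31%'),
 ('none', '100%', '100%', '100%')]
```

That is: 877 of 900 seedlings correctly screened (23 errors), with every
no-seedling frame recognised.

Training and whole-frame screening:

```
seedlingscreen train --manifest data/manifest.csv --arch custom --lr 1e-4 --epochs 10 --seed 7 --out model.npz
seedlingscreen run --frame frame.png --method cnn --model model.npz --arch custom --out verdicts.jsonl
```

`run` prints one JSON verdict per station (left to right) with a
`remove_flag` for every non-healthy position.

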