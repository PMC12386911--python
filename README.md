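# crowndetect

Detection toolkit for UAV-based conifer crown-health surveys.

Forest-health monitoring campaigns fly drones over pine stands attacked
by wood-boring pests (e.g. the Sirex woodwasp) and need to find, in RGB
imagery, the trees whose crowns show decline: yellowing, thinning
canopies (**Weak**) and bare grey-brown canopies (**Dead**), against a
background of healthy trees that are never annotated.  The imagery mixes
nadir orthophotos (small, near-square crown boxes) with oblique views
(tall boxes with height/width 2–5), which stresses both the feature
extractor and the box-regression loss.

`crowndetect` provides, as a tested library plus CLI:

- **StripBlock / C3k2Strip** — backbone blocks that factor spatial mixing
  into directional depthwise strips (1×k and k×1, k = 10) with a
  multiplicative attention gate and a dual residual with learnable layer
  scales;
- **CAA / C3k2CAA** — sigmoid-gated channel-aware context attention for
  the feature-fusion neck;
- **SDIoU** — a size-adaptive IoU-family box similarity,

      SDIoU = (δ−β) + (1−δ+β)·IoU − α·v − (1+δ−β)·ρ²/c²,
      β = δ·(1 − log(1+area)/log(1+S_max)),   δ = 0.5,  S_max = 90²,

  which strengthens supervision for small targets and relaxes it as the
  target approaches the reference area, with the usual aspect-ratio term
  α·v and centre-distance term ρ²/c²;
- a pico-scale anchor-free **detector** (backbone + PAN neck + per-cell
  head at strides 8/16/32) trained with BCE + SDIoU loss, with
  independent ablation toggles for the three components;
- **metrics** — precision/recall/F1 and all-points-interpolated AP/mAP at
  IoU 0.5, with PR curves and a text report format;
- a **ground-survey validation** procedure: strict 0.60 confidence
  filtering, point-in-Weak-box matching of surveyed damaged trees, and
  the accuracy rate AR% = 100·SD/DT;
- **annotation I/O** — LabelImg Pascal-VOC XML and YOLO text labels, and
  the 7:3 split utility;
- a seeded **synthetic scene generator** that renders crowded crowns in
  both capture regimes so that every component is testable without any
  field imagery.

The network stack runs on a small reverse-mode autodiff engine over
numpy (`crowndetect.nn`); there is no GPU or deep-learning-framework
dependency.

## Worked example

Train the pico detector on synthetic scenes, evaluate it, and validate
against a survey-point file:

```bash
crowndetect generate --out data/demo --n 20 --seed 7 --image-size 128
crowndetect train --out runs/demo --n-train 200 --n-val 50 \
    --epochs 30 --image-size 128 --seed 0
crowndetect eval runs/demo/best.ckpt.npz --out runs/demo/eval --seed 1
```

The training log ends with lines like

```
{"epoch": 29, "loss": 0.5922, "box_loss": 0.0959, "cls_loss": 0.1125, ...}
best val mAP@0.5 = 0.8332 (epoch 29)
```

- `box_loss` is the mean `1 − SDIoU` over assigned cells — 0.11 means
  the decoded boxes sit close to their targets;
- `cls_loss` is the weighted binary cross-entropy of the class maps;
- `mAP@0.5` is the mean of the Weak and Dead average precisions on the
  50 held-out scenes (exact value varies with the seed).

Survey validation runs from a checkpoint or from a precomputed
detections CSV.  With the campaign-shaped example fixture (70 previously
damaged trees of which 68 are covered by a retained Weak box, 11/10
newly damaged):

```bash
crowndetect survey points.csv --detections dets.csv --conf 0.60
```

```
Category             DT  SD  AR (%)
Model detected Weak  92  -   -
Model detected Dead  20  -   -
previously damaged   70  68  97.14
newly damaged        11  10  90.91
overall              81  78  96.30
```

AR is the share of ground-surveyed damaged trees covered by a retained
Weak detection; the overall rate pools counts (78/81), it is not the
mean of the category rates.

## Layout

```
src/crowndetect/
  nn/            autodiff tensor engine, layers, SGD
  boxes.py       AxisBox, IoU, SDIoU similarity and loss
  strip.py       StripBlock and its container
  caa.py         channel-aware attention and its container
  detector.py    assembly, assignment, loss, decode, checkpoints
  train.py       training loop, evaluation, smoke protocol
  metrics.py     matching, P/R/F1, AP, mAP, reports
  synthetic.py   seeded UAV forest-scene generator
  survey.py      confidence filter, point matching, AR reports
  dataset_io.py  VOC XML, YOLO labels, splits, class maps
  cli.py         generate / train / eval / detect / survey
```

See `docs/methods.md` for the model details, parameter defaults, the
design decisions taken where the formulation left room, and what the
synthetic benchmark does and does not demonstrate.
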