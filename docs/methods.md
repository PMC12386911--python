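# Methods

`crowndetect` is a desk-scale re-implementation of a single-stage detector
for conifer crown health in UAV imagery, together with the evaluation
statistics, annotation formats, ground-survey validation procedure, and a
synthetic scene generator that stands in for field imagery.  This note
records the models, the parameters that matter, and the design decisions
taken where more than one reasonable choice existed.

## The detection problem

Wood-boring pests such as the Sirex woodwasp attack weakened pines; the
canopy-level signs are a yellowing, thinning crown (*Weak*) and, later, a
bare grey-brown crown (*Dead*).  Surveys fly two capture regimes: nadir
orthophotos, in which crowns are small and near-square, and oblique
passes, in which crowns are tall with height/width ratios of 2–5.
Healthy canopy is not annotated — the detector must treat it as
background.  Class ids are fixed: Weak → 0, Dead → 1.

## Network components

**StripBlock** (backbone).  Spatial mixing is factored into directional
depthwise convolutions — a 5×5 local aggregate, then a horizontal 1×k and
a vertical k×1 strip with k = 10 — whose 1×1-projected output gates the
block input multiplicatively (Strip Attention).  A pointwise-expand /
depthwise-3×3 / GELU / pointwise-reduce branch mixes channels (Strip
MLP, expansion 4).  Both branches are combined in a *parallel* dual
residual with per-channel learnable layer scales:

    out = x + γ1 · Attn(BN1(x)) + γ2 · MLP(BN2(x))

γ is initialised to 1e-2 (standard layer-scale practice).  Because k is
even, "same" padding is asymmetric — floor((k−1)/2) leading, ceil((k−1)/2)
trailing — and shape preservation is tested for every spatial size ≥ 1.
A sequential (metaformer-style) residual is a documented alternative; the
parallel form is what the defining equation states, and it is what we
implement.  The 5×5 depthwise convolution carries no extra normalisation
or activation.

**CAA** (neck).  A channel-aware attention unit squeezes local context
with a stride-1 7×7 average pool (padding 3; a *global* pool would
collapse the map and leave nothing for the directional convolutions to
act on), applies 1×1 → DW 1×k → DW k×1 → 1×1, and gates the unit input
through a logistic sigmoid.  The gate is bounded in (0, 1), so the unit
can only attenuate — |CAA(x)| ≤ |x| elementwise, which is tested.  The
`C3k2CAA` container fuses the input with n parallel CAA views by one
pointwise convolution over (n+1)·C channels.  The strip order differs
between the two blocks on purpose: Strip Attention applies 1×k before
k×1, CAA applies them in its own stated order; each follows its defining
composition.

**Containers.**  Both custom blocks sit inside the split/transform/
concat/fuse container pattern of the YOLO11 family ("C3k2"): a pointwise
convolution splits the input into two hidden streams of c_out/2 channels,
one stream runs the blocks, and a pointwise fusion recombines.  The
baseline container used by the ablation toggles replaces the blocks with
plain 3×3 conv-BN-SiLU units.

## SDIoU

For a predicted box b1 and target b2 (centres, widths, heights in px):

    v     = (4/π²)(arctan(w2/h2) − arctan(w1/h1))²
    α     = v / (1 − IoU + v)            (α·v ≡ 0 when v = 0)
    β     = δ·(1 − log(1+area(b2)) / log(1+S_max)),  clamped to [0, δ]
    SDIoU = (δ−β) + (1−δ+β)·IoU − α·v − (1+δ−β)·ρ²/c²

with δ = 0.5, S_max = 90² px² (the largest labelled orthophoto target at
the 640×640 input resolution), ρ² the squared centre distance and c² the
squared diagonal of the smallest enclosing box.  Conventions chosen where
the formulation is silent: natural logarithm (the ratio makes the base
immaterial); the training loss is 1 − SDIoU; α and β are treated as
non-differentiable coefficients, as is conventional for the analogous
CIoU term; degenerate boxes are rejected rather than epsilon-patched, and
the training decode clamps sizes to a positive floor before the loss sees
them.  Small targets (area ≪ S_max) receive β ≈ δ, which both raises the
weight of the IoU and centre-distance terms; the tests verify that the
centre gradient under 1 − SDIoU exceeds the plain 1 − IoU gradient for
small targets at low IoU.

## Detector assembly and training

The compute core is a reverse-mode autodiff tensor engine written in
numpy inside `crowndetect.nn` (convolutions via strided-window
contractions and per-tap scatter; gradients verified against finite
differences).  The detector is anchor-free with three pyramid strides
(8, 16, 32).  Each level's head is a shared 3×3 trunk feeding *decoupled*
box and class branches; with a coupled head, one class channel can
collapse into the box-objectness solution on some initialisations and
never recover.  Per cell the head predicts 4 box offsets and per-class
sigmoid scores; decoding is

    cx = (gx + 2σ(tx) − 0.5)·s,   w = exp(tw)·s   (tw clamped to [−6, 4])

Targets: each ground-truth box picks the level whose stride best matches
its size (≈4 cells per side) and claims the cells whose centres fall in
its central half, plus the centre cell; first box wins contested cells.
The loss is `cls_w · BCE + box_w · mean(1 − SDIoU)` over assigned cells
(weights 1 and 5).  BCE is computed densely with a *cell-level* weight:
all class channels of an assigned cell carry weight 20, background cells
weight 1.  Weighting only the positive targets instead (a per-target
pos-weight) makes lighting up the wrong class nearly free and the head
degenerates into predicting objectness on every channel; the cell-level
weighting is what makes the two classes separable in training.

The head parameterisation, the centre-region assignment and the absence
of a distribution-focal component are deliberate simplifications: the
contribution being isolated is the loss and the two blocks, not head
engineering.  Ablation toggles swap strip→plain, CAA→plain and
SDIoU→plain-IoU independently; all eight combinations build and train.

Full-scale training defaults mirror the study regime (SGD, lr 0.01,
momentum 0.8, batch 16, 300 epochs, 640 px input) and are retained in
`TrainConfig` as documented defaults.  The desk-scale smoke protocol used
by the tests and the acceptance script trains the default pico width
(~0.5 M parameters) at 128 px input, batch 4, 30 epochs, with a 3-epoch
linear warmup and half-cosine decay of the learning rate to a tenth;
scene geometry
(crown sizes, the 90 px ortho cap) is scaled with the input resolution so
the object/stride ratios match the full-resolution regime.  Momentum 0.8
is unusually low for SGD but is kept as the study states it.
Evaluation decodes at a low confidence floor (0.05) so the PR sweep
covers the full recall range; the deployment threshold (0.25 default,
0.60 for survey work) is a separate concern.

## Metrics

Per class, detections are sorted by descending confidence and greedily
matched to the unmatched same-class ground-truth box of highest IoU
≥ 0.5, ties broken by first index; duplicate hits are false positives.
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) with 0/0 → 0.  AP is the
area under the all-points-interpolated precision envelope versus recall
(not the 11-point variant), and mAP is the unweighted mean over classes
at the single IoU threshold 0.5, the convention of the surrounding
detector literature.  Because a single F1 requires choosing an operating
point, the report states F1 at the confidence that maximises it.  A
"pooled" aggregate that merges both classes into one matching problem is
reported alongside per-class APs for dataset-level summaries.

## Survey validation

Detections are filtered by confidence *strictly greater than* 0.60.
A survey point (a tree position, not a box) counts as successfully
detected when it lies inside at least one retained box of the Weak class
in its image — survey targets are weakened, living trees, so Dead boxes
do not match by default (the gate is configurable); containment is
boundary-inclusive.  AR% = 100·SD/DT, rounded half-up to two decimals;
the overall rate pools counts (ΣSD/ΣDT), it is not the mean of category
rates.  The toolkit reproduces the campaign arithmetic 68/70 → 97.14 %,
10/11 → 90.91 %, 78/81 → 96.30 % from a geometric fixture that encodes
those counts as points and boxes and runs the full pipeline.

## Synthetic scenes

The generator emulates the study imagery it stands in for: crowded tree
crowns in three visual health classes over textured green/brown clutter,
in both capture regimes (ortho: aspect 0.8–1.25, annotated boxes capped
at 90 px at 640 px resolution; oblique: aspect 2–5 with partial trunk).
Crowns are layered soft ellipses with class-specific palette and speckle
density (healthy: dense dark green; weak: sparser yellow-green, thinned
top third; dead: sparse grey-brown with radial branch spokes).  Palettes
are fixed named constants, jittered ±8 % per tree and recorded in the
dataset manifest.  Later-drawn crowns occlude earlier ones up to a
pairwise box-IoU budget (default 0.3); annotations cover the *visible*
extent, computed from a per-pixel ownership buffer, because annotators
box what they see.  Healthy crowns are rendered but never annotated.
All randomness comes from one generator seeded per scene, so a
(config, seed) pair is bit-reproducible, which the tests assert.

What the generator does **not** emulate: real crown texture and shadow,
atmospheric and exposure variation, other broadleaf species, trunk-level
symptoms invisible at canopy scale, and georeferencing.  Passing the
smoke-learnability test therefore shows that the architecture, loss,
assignment, decoding and training loop are wired correctly and can fit a
structured detection task — it says nothing quantitative about accuracy
on real UAV imagery.

## Numerical and procedural choices

- float32 throughout the network; float64 in scalar box arithmetic.
- Batch normalisation: running statistics with momentum 0.1; the pico
  scale trains with batch 4, so eval-mode inference relies on those
  running estimates.
- NMS: per-class, greedy, IoU threshold 0.45.
- Letterboxing: aspect-preserving resize with gray (114) padding; origin
  top-left, pixel centres at integer + 0.5.
- VOC XML corners are read as 1-based inclusive pixel indices (LabelImg
  dialect): (1, 1, 100, 50) → centre (50.0, 25.0), size (99, 49).
- 7:3 split: seeded shuffle, train size = round(0.7·n), per image.
- The split of 1330 retained images gives 931/399.
- Checkpoints: single `.npz` with a JSON config snapshot and a format
  version field.

## Known limitations

- The numpy compute core is single-threaded and desk-scale; the 640 px
  full-width configuration builds and runs but is not intended for real
  training campaigns.
- Greedy confidence-ordered matching can in principle differ from the
  globally optimal assignment on adversarial overlap structure; the
  tests compare it against exhaustive search on small random instances.
- The synthetic mAP figures are not comparable to results on real
  imagery (see above); the survey-validation module reproduces the
  campaign arithmetic, not the campaign's detections.
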