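# Methods

This note documents the models, conventions and design choices behind
`seednet`, including everything that was genuinely open and how it was
fixed.

## Model family

All variants share the 50-layer bottleneck skeleton: 7×7/2 stem conv (64
channels) + BN + activation + 3×3/2 max pool; four stages with block counts
(3, 4, 6, 3) and mid channels (64, 128, 256, 512), bottleneck expansion 4;
global average pooling; fully connected head (2048 → classes, with bias).
Stage 1 runs at stride 1 (its first block still projects 64→256); stages
2–4 open with a stride-2 block. Projection shortcuts are 1×1 strided conv +
BN; strides live in the 3×3 (or depthwise) convolution.

`VariantConfig` toggles three rewrites:

* **ResStage (early stages, mid 64 and 128).** Start block:
  conv–BN–act ×2, conv–BN, bare addition. Middle blocks: pre-activation
  (entry BN–act, then conv–BN–act ×2, conv), bare addition. End block: like
  Middle, then BN and the stage's trunk activation *after* the addition.
  The block directly following a Start block skips its entry BN (the Start
  branch already ends in one). This bookkeeping makes the BN census of a
  stage identical to the baseline's (3n norms with matching channel
  widths), so the rewrite changes the trainable-parameter count by exactly
  zero — a property the tests assert. On the shortcut trunk a ResStage
  stage carries one activation regardless of depth; the per-block counts of
  the baseline (one per addition) are what this removes. A network with all
  four stages reorganized carries exactly four trunk activations. Note that
  the individual Start/Middle/End blocks do *not* each match the baseline
  block's parameter count (the End block holds one extra norm, the
  first Middle one fewer); only the stage total does, which is the quantity
  that matters for the reported model sizes.
* **Improved blocks (later stages, mid 256 and 512).** Post-activation
  bottlenecks whose branch is 1×1 conv–BN–act, ECA gate, depthwise 3×3
  conv–BN–act, pointwise 1×1 conv–BN, 1×1 conv–BN, addition, trunk
  activation. The ECA gate sits after the first convolution's norm and
  activation; its kernel width is derived from the branch's mid channel
  count (k=5 at both 256 and 512). The attention conv carries no bias and
  zero-pads to preserve length, so it adds exactly k parameters. The
  depthwise-separable pair replaces 9m² conv weights by 9m + m² and adds
  one BN(m); per later-stage block this removes ≈0.52 M (m=256) and
  ≈2.09 M (m=512) parameters, ≈9.40 M in total — the gap between the
  23.52 M and 14.12 M configurations.
* **Mixed activations.** Swish at the stem activation and at every
  post-addition site (End blocks, improved blocks); PReLU at all other
  sites; plain variants use ReLU everywhere. Each PReLU site owns a single
  shared learnable slope (α₀ = 0.25) rather than per-channel slopes: the
  whole network gains only a few dozen scalars, so toggling mixed
  activation never moves a parameter count reported in rounded millions —
  matching the published ablation table, where activation-only variants
  print the baseline count.

A widely printed form of the parametric rectifier
(`0 for x ≤ 0, αx for x > 0`) describes a scaled ReLU; the curve and the
original reference define PReLU as identity on the positive branch and αx
on the negative branch, which is what `seednet.activations` implements.

## Complexity accounting

`seednet.complexity` derives counts from layer hyperparameters and symbolic
shape propagation — nothing is measured at run time, so results are exact,
weight- and batch-independent. Parameters: sum of trainable tensor sizes.
MACs for one forward pass, inclusive convention:

| layer | MACs |
|---|---|
| conv (incl. depthwise/pointwise/1-D) | output positions × kernel volume × C_in/groups (+ bias) |
| fully connected | in × out (+ out) |
| batch norm (affine) | 2 / element |
| ReLU / PReLU | 1 / element |
| Swish | 2 / element (sigmoid + product) |
| pooling | kernel volume per output position (for global average pooling this equals the input element count) |
| ECA | pool + width-k conv + sigmoid + per-element gate |

Elementwise shortcut additions are not counted. A `conv_fc_only` mode
restricts to convolution/fully-connected work for comparison with stricter
tools. Reported values round half-away-from-zero to two decimals. This is
the unique uniform convention in the family we considered under which all
four printed model figures (4.12, 3.20 and 4.13 GMac, and the 0.92 GMac
reduction) hold simultaneously at two decimals; the elementwise terms total
≈0.8 % of the budget, so the choice is cosmetic for any practical
comparison.

## Segmentation pipeline

Grayscale is ITU-R 601 luminance (0.299 R + 0.587 G + 0.114 B). "Automatic
global thresholding" is implemented as between-class-variance maximization
(Otsu), with a fixed-threshold escape hatch. Mask cleanup: morphological
opening then closing with disk structuring elements (default radius 3 px
each), hole filling, and rejection of components below `min_area`
(default 400 px²). Components are labeled with 8-connectivity; each
surviving component yields one crop of fixed size (default 224×224)
centered on its centroid, padded with `background_fill` at scene edges, and
crops are ordered row-major by centroid. Touching seeds form one component;
no watershed splitting is attempted. The dataset split rule is per-class
ceiling 80/20 (`train = ceil(0.8·n)`), the only rounding consistent with
the published per-class partition (e.g. 998 → 799/199); on the six
published class totals it yields 4703 training and 1174 validation images.

## Training and evaluation

SGD with classical momentum (0.9) and weight decay (5e-4) on softmax
cross-entropy with mean reduction (the published loss magnitudes require
mean reduction); defaults epochs 150, batch 32, lr 1e-3. Stratified 5-fold
cross-validation via scikit-learn; the validation fold doubles as the test
set (as in the study protocol — a caveat for generalization claims), and
reported metrics are final-epoch values averaged over folds. Evaluation
reports a confusion matrix (rows = true), accuracy, and per-class
precision/recall/F1; a class never predicted reports precision 0 with a
warning. Grad-CAM uses the spatially averaged gradient of the target-class
logit as channel weights on a chosen stage's output feature maps (default:
the last stage, i.e. the last convolution's output after its block),
rectifies the weighted sum, bilinearly upsamples to the input size, then
min–max normalizes (normalizing after upsampling keeps the contract
min = 0, max = 1 exact; a constant map returns all zeros).

## Synthetic data

No public accession of the photographed six-variety dataset exists, so the
generator emulates its geometry rather than its appearance: one ellipse per
crop (random orientation, class-dependent eccentricity range) filled with a
class base colour modulated by a class-specific sinusoidal texture
(amplitude 0.15), additive Gaussian pixel noise (σ = 6 gray levels), dark
background (level 12); scenes place disjoint ellipses (rejection sampling
with a safety margin, ≤1000 attempts, honest count on failure) and record
mask/centroids. The palette keeps every class's luminance ≳110 so the
seed/background histogram is genuinely bimodal — the regime the
thresholding step is designed for — while classes remain separable by mean
colour (a nearest-centroid oracle on mean RGB scores >0.9, which is what
makes the small-scale training sanity thresholds meaningful). What passing
tests on this data do **not** show: robustness to real-world illumination,
shadows, touching kernels, intra-variety variation or camera noise; the
published real-data accuracies are out of reach without the original
dataset and GPU-scale training, and are not claimed.

## Problem sizes in the test suite

The suite must run on one CPU in minutes, so training checks scale the
*data*, never the architecture: the trainability check trains the full
improved model (14.12 M parameters) on 240 synthetic crops rendered at
64×64 for 5 epochs (batch 16, lr 5e-3 — a small-input, small-sample choice;
the protocol defaults target the full-size task) and requires >0.8 held-out
accuracy; the label-permutation control reuses the same pipeline and must
score within ±0.06 of chance (1/6) on a fresh 240-crop balanced sample
(evaluating on 240 rather than the 48 held-out crops keeps the chance band
at ≈2.5σ). Grad-CAM localization is scored on 128×128 crops (4×4 feature
maps at the default layer) with the trained model, requiring ≥50 % of
top-decile heatmap mass inside the generating ellipse, averaged over 20
images. Scene-count recovery runs 20 scenes at the generator's default
1024² size. Gradient correctness is established by central-difference
checks on every layer type in float64.

## Known limitations

* CPU numpy training is practical only at reduced input sizes; the code is
  correct at 224² but slow there.
* Batch-norm statistics after 5 small epochs are rough; evaluation uses
  running statistics, which slightly depresses small-scale accuracy.
* The checkpoint format stores weights and running statistics as `.npz`
  plus a JSON sidecar of the variant configuration; optimizer state is not
  persisted.
* Scenes with overlapping kernels are intentionally out of scope for the
  segmenter (one component per contact group).
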