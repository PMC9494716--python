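# Methods

`cellseg` implements a label-efficient pipeline for segmenting and
counting two cell populations — red blood cells (RBCs, class 1) and
macrophage-like adherent cells (class 2) — in bright-field microscopy
crops.  Manual pixel annotation is the bottleneck for training a
semantic segmenter, so training labels for *single-kind* images (a dish
containing only one cell type) are generated automatically by classical
image processing; a U-Net is pretrained on those free labels and then
fine-tuned on a small manually labeled *mixed* set.  Cell counts are
read off the predicted masks by connected-component analysis.

## 1. Automatic label generation

For a single-kind image the class of every cell is known, so
segmentation reduces to foreground extraction:

1. **Gaussian filtering.**  A normalized `3x3` kernel with sigma 0.8
   per axis (defaults), reflective borders, suppresses sensor noise
   before edge-sensitive steps.
2. **Adaptive thresholding.**  The threshold at each pixel is the
   Gaussian-weighted mean of a `w x w` window minus an offset `C`
   (default 2).  A pixel is foreground iff strictly darker than its
   threshold (polarity configurable; ties are background).  When no
   sigma is given the window sigma follows the classical rule
   `0.3*((w-1)/2 - 1) + 0.8`, which reproduces sigma 0.8 at `w = 3`.
   Local thresholding absorbs smooth illumination gradients that defeat
   a global threshold.
3. **Contour detection.**  Outermost closed borders of 8-connected
   foreground components are traced with Moore-neighbor border
   following (Jacob's stopping criterion); interior holes have no
   border of their own.  Components whose *filled* area is below
   `min_area` are discarded as impurities or broken cells.
4. **Morphological processing** (optional, on by default in the
   synthetic presets).  The filled mask is opened — erosion then
   dilation, Eqs. dst(x,y) = min/max over the kernel support — which
   removes thin structures: debris fibers and the bridges that
   thresholding draws between adhesive macrophages.  Contours are
   re-extracted, re-filtered, and re-filled.
5. **Contour filling.**  Each contour is rasterized and everything it
   encloses is filled, so hollow detections (large cells whose interior
   is brighter than the local threshold) come back solid.

The filled mask, tagged with the image's class value, is the training
label.

Fixed numerical conventions the classical literature leaves open:
reflective borders for convolution and thresholding, replicate borders
for morphology; strict inequality at the threshold; contour areas are
filled areas; filling closes holes per contour, never jointly across
contours; contours are ordered by their top-left-most starting pixel.

### Preset geometry

The defaults mirror a 3x3-kernel recipe.  For the synthetic scenes the
`preset_for_kind` presets derive their parameters from the cell
geometry instead:

- threshold window `2*r_max + 1` of the kind's cell class — wide enough
  that a window centered on a cell always sees background, so cell
  interiors are not hollowed more than filling can repair;
- `min_area = pi*r_min^2 / 2`, half the smallest true cell area;
- disk-shaped opening footprints: radius 2 for RBC scenes (removes
  ~2-3 px debris fibers while discs of radius >= 3 survive), radius 3
  for macrophage scenes (additionally removes the <= 5 px adhesion
  bridges).  A disk SE nearly commutes with disc-shaped cells, unlike
  the square default, so opening costs almost no IoU on round cells.

## 2. Synthetic scenes

The generator emulates the statistical structure of 8-bit bright-field
crops so every stage is testable without the original data:

- **Cells** are filled ellipses with jittered axes: RBCs radius 4-6 px,
  macrophages 10-16 px at the default 256x256 scale (preserving the
  ~2.5x size ratio of 5-7 um RBCs vs 13-20 um macrophages; the px/um
  factor is a free choice).  Cells are darker than background (means
  95/120 vs 185) with +-6 per-cell jitter; polarity of the labeler is
  configurable.  Placement is rejection-sampled under a no-overlap
  policy with a 3 px minimum gap; a scene whose requested counts cannot
  be placed is redrawn deterministically.
- **Adhesive macrophage pairs** (probability 0.1 per placement; "some"
  macrophages adhere) are modeled as two flattened circles whose
  centers sit at 0.97x the sum of their nominal radii and whose drawn
  bodies stay 3.5 px apart, joined by a thin strip of cell material
  (the adhesion interface, ~2-3 px wide, drawn in both image and truth
  mask).  Two overlapping bodies were rejected as a model because
  morphological opening provably cannot disconnect two overlapping
  discs (the opening contains each disc unchanged); the thin-bridge
  geometry is the one in which erosion-then-dilation genuinely
  separates touching cells, and it makes the behavior deterministic:
  without morphology every pair is one component, with it every scene
  counts exactly.
- **Debris fibers** — thin (2.5 px) dark streaks long enough to pass
  the area filter — appear with per-kind probability (0.1 RBC scenes,
  0.5 macrophage, 0.3 mixed; the cultured macrophage line accumulates
  more debris than fresh-blood RBC preparations).  They are drawn on
  the image only and give the morphological-opening ablation its
  second mechanism.
- **Noise and illumination**: additive Gaussian noise (std 8) and a
  random-direction linear gradient (amplitude 15) on top.
- **Contrast contract**: with zero noise, zero gradient and no debris,
  a global threshold at the midpoint of mean cell and background
  intensity recovers the foreground mask exactly.

What the generator does **not** emulate: point-spread blur and defocus,
the bright halo ("dark ring") appearance of defocused RBCs,
out-of-plane cells, overlapping cells of different classes, staining
variation, JPEG artifacts.  Passing tests therefore demonstrate the
internal consistency of the pipeline under its own model of the data,
not performance on real microscopy.

## 3. Segmentation network

A standard U-Net: per encoder stage two 3x3 same-padding convolutions
with ReLU, then 2x2 stride-2 max pooling; the decoder mirrors each
stage with nearest-neighbor 2x upsampling, a 3x3 convolution halving
the channels, concatenation with the same-level encoder features, and
two further convolutions; a 1x1 head maps the first-stage width to the
3 class logits.  No batch normalization.  Weights are He-initialized
(zero-mean Gaussian, variance 2/fan-in), biases zero.  The
`vgg16-first-12` preset lays the encoder out as the first 12
convolutions of VGG16 (2+2+3+3 per stage at widths 64-512 plus the
bottleneck) and can load externally supplied pretrained weights; all
tests run with random initialization.  An optional `bottleneck_factor
= 4` switch replaces the deepest pooling/upsampling pair with 4x.

Forward and backward passes are written directly in numpy (float32,
im2col + BLAS matmul), with analytic gradients for every layer and for
the combined loss.  Correctness is pinned by central-difference
gradient checks in float64; note that finite differences disagree with
the exact subgradient at ReLU kinks, which zero-initialized biases hit
systematically (an all-zero padded receptive field outputs exactly 0),
so the checks randomize biases.

The depth-3 "tiny" variant (widths 8/16/32/64, ~134k parameters)
trains on one CPU core in minutes; the depth-4 paper-scale preset
(widths 32-512) is the same code.

## 4. Loss and training

The loss couples per-pixel cross-entropy `H` with a soft Jaccard term:
`L = H - log J`, where per foreground class `c` present in the truth

    J_c = (sum p_c y_c + 1) / (sum p_c + sum y_c - sum p_c y_c + 1)

with one-hot truth `y`, eps = 1 smoothing, and `J` the mean of the
`J_c`.  Background is excluded from `J` by default (it would dominate
the term); a flag restores it.  The identity `L = H - log J` holds
exactly for every logged training step.

Optimization is Adam (beta1 = 0.9, beta2 = 0.999), batch size 4,
learning rate 1e-3 for pretraining and half that (5e-4) for
fine-tuning, no schedule, best-validation-mIoU checkpointing.
Augmentation applies one random rotation (+-30 deg) and isotropic scale
(0.9-1.1) to image (bilinear) and mask (nearest-neighbor, classes
preserved) plus a gray shift (+-20) to the image only.  Fine-tuning
trains all layers; an encoder-freeze option exists in config space but
is off because nothing suggests freezing.  Training is bit-reproducible
under a seed.

## 5. Counting

Per class value, 8-connected components of the predicted mask are
extracted; components smaller than a per-class minimum area (default:
half the smallest true cell area) are dropped as false positives; each
survivor counts as one cell.  The optional `split_large` policy counts
a component larger than 1.5x a typical cell area as
`round(area/typical)` cells; it is off by default because merged blobs
are already handled upstream by morphological opening in the labels.
Components touching the image border are flagged (border cells are the
dominant under-count mechanism).  Count accuracy is reported as
predicted/truth per class in percent, n/a for zero truth.

## 6. The three training regimes, scaled down

The experimental structure is replicated at desk scale on 64x64
synthetic scenes (RBC radius 3-5 px, macrophage 6.5-10 px) with the
tiny U-Net:

- **U-Single**: pretrain 20 epochs on 200 auto-labeled single-kind
  scenes (100 RBC + 100 macrophage), validated for checkpointing on 20
  auto-labeled holdouts (no manual truth is assumed at this stage);
- **U-Transfer**: fine-tune 10 epochs on 10 truth-labeled mixed scenes
  at half the learning rate, 5 truth-labeled validation scenes;
- **U-Base** (optional flag): train from scratch on 40 truth-labeled
  mixed scenes.

All regimes are evaluated on the same 30 held-out mixed scenes against
generator ground truth: micro-averaged mIoU / FWIoU (confusion matrices
summed over images; a macro flag averages per image instead), mean
foreground Dice, and per-class count accuracy.  The acceptance suite
runs three seeds and takes medians.  These sizes are the package's
default `ProtocolConfig`; they were chosen so a full three-seed run
completes in CPU minutes while preserving the pretrain-then-fine-tune
structure and the ordering it is meant to demonstrate
(transfer >= single on mixed-scene mIoU).

## 7. Known limitations

- The Moore tracer returns one outer contour per component; a contour
  may legitimately revisit pixels on 1-px-wide structures.
- mIoU excludes classes absent from both masks (0/0); the
  `strict_k_plus_1` flag restores the literal divide-by-(k+1) form.
- The numpy network is single-core and eager; it is meant for tests
  and desk-scale studies, not production GPU training.
- Counting treats every surviving component as one cell; heavily
  clustered cells beyond pairwise adhesion are out of the generator's
  and the counter's model.
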