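# Methods

## Model

The detector is a one-stage prototype-mask instance segmenter.  A residual
backbone produces stage maps at strides 8/16/32; a feature pyramid projects
them to a common width with 1×1 lateral convolutions, adds the upsampled
(nearest-neighbour, ×2) higher level, applies the pixel self-attention (PSA)
block to each merged map, and smooths with a 3×3 convolution into P3–P5.
P6/P7 come from stride-2 3×3 convolutions on P5/P6 and carry no attention.
A ProtoNet (two 3×3 convs, one ×2 upsample, a 3×3 conv, and a final 1×1 to
k maps, all ReLU-gated) turns P3 into k nonnegative prototype masks at one
quarter of the input resolution.  Heads shared across levels emit, per
anchor, background+foreground logits, four SSD-encoded box offsets
(center-offset / log-size with variances 0.1/0.2), and k tanh-squashed mask
coefficients.  Inference decodes boxes, thresholds scores at 0.05, runs
classic greedy per-class NMS at IoU 0.5 (ties break toward the lower anchor
index for determinism), combines prototypes with each survivor's
coefficients, applies a sigmoid, bilinearly upsamples to image size, crops
to the predicted box, and binarizes at 0.5.

### PSA

Both branches halve channels (reduction factor 2, exposed in config).  The
pairing of the flattened value map with its softmax-normalized query — and
of the channel softmax with the flattened spatial values — is implemented as
tensor contraction over the shared axis; that is the only composition whose
outputs have the declared shapes (a C-vector channel gate, an H×W spatial
gate).  The squeeze in the spatial branch is global *average* pooling, the
convention for squeeze-style attention, which also keeps the softmax input
scale bounded.  The channel-restoring 1×1 convolution carries a bias and no
normalization layer; no layer normalization is inserted between contraction
and sigmoid.  PSA parameters are independent per pyramid level, so each
receptive-field scale learns its own filtering.  All 1×1 kernels use
zero-mean fan-in-scaled (Kaiming) initialization with zero biases, seeded.

### Design decisions that were genuinely open

- **Crop gating.**  Assembled masks are cropped to their predicted box only
  when the box covers less than a quarter of the image (configurable);
  large instances keep their full mask.  Size-conditional cropping needs
  *some* threshold, and 0.25 preserves the intent — protect small objects
  from prototype bleed-through — without truncating large bodies.
- **NMS flavour.**  Classic greedy NMS, because it admits an exact O(n²)
  brute-force oracle; a fast approximate variant would trade testability
  for speed the desk-scale models do not need.
- **k = 32 prototypes, tanh coefficients, mask threshold 0.5, pyramid width
  256, anchor scales {24,48,96,192,384} with ratios {1, 1/2, 2}** — the
  standard choices for this detector family, all in config.  The tiny
  preset scales anchors by 1/4 and uses k=8, width 64.
- **C3–C5 feed the pyramid** (not C1/C2): stride-8 is the finest level the
  mask head consumes; feeding stride-2/4 maps would quadruple memory for no
  tested benefit.

## Training

SGD with momentum 0.9 and weight decay 5·10⁻⁴; the full-scale default is
lr 0.001, batch 8, 50 epochs, with images standardized per channel by mean
(123.675, 116.28, 103.53) and std (58.395, 57.12, 57.375).  Anchors are
positive at IoU ≥ 0.5 to their best ground truth and negative below 0.4;
the band between is ignored.  Each ground truth additionally claims its
best still-unclaimed anchor, so every instance owns at least one positive.
Losses: softmax cross-entropy with online hard-negative mining at 3:1
negatives:positives; smooth-L1 on encoded offsets of positives; per-pixel
binary cross-entropy between the (cropped, pre-threshold) prototype
combination and the matched mask at prototype resolution, normalized by the
ground-truth box area; total = L_cls + 1.5·L_box + 6.125·L_mask.  A global
gradient-norm clip of 10 guards the small-batch runs.  A linear
learning-rate warmup is available (off in the full-scale default; the tiny
preset uses 20 steps) — warmup is itself deterministic, so runs remain
exactly reproducible from the seed.  Training aborts with a diagnostic
naming the epoch, batch, and loss term if any loss goes non-finite.

Three numerical choices matter in practice.  The engine computes in float32
(float64 is available via a context manager and is used by the
finite-difference gradient checks).  The ProtoNet's final bias is
initialized at +0.5: with a ReLU-gated prototype layer, an initialization
that starts all prototypes negative receives zero gradient forever, and
small-width models can land there; the positive bias keeps the layer alive.
And the tiny preset's 20-step warmup tames the violent first epochs of
small-batch training, which can otherwise drive the prototype layer into
the same dead-ReLU state mid-run.

The desk-scale overfit preset trains the tiny backbone (3 basic-block
stages, widths 32/64/128, no normalization layers — at these widths
fan-in-scaled init suffices) on 8 generated 64×128 scenes for 200 epochs at
lr 0.02.  The full-scale lr 0.001 is a large-batch multi-GPU setting; a
35k-parameter model fitting 8 images needs a larger step to converge in 200
passes.  Problem sizes throughout (8 scenes, 64×128, k=8, width 64) are the
package's desk-scale choices so the whole suite runs on one CPU core.

### Augmentation

Seven stochastic operations fire independently per sample in fixed order:
shift/scale/rotate (shift ±6.25% of each dimension, p=0.5), brightness/
contrast (±10–30%, p=0.2), RGB shift (±10 per channel, p=0.1), HSV shift
(±20/30/20 in OpenCV-style units, p=0.1), JPEG re-encoding (quality 85–95,
p=0.2), channel shuffle (p=0.1), and 3×3 median blur (p=0.1).  Geometric
transforms move image and masks together (linear vs nearest interpolation);
boxes are recomputed as tight boxes of the transformed masks, and instances
whose visible area vanishes are dropped.  The scale/rotation strength
"0.1–0.3" is read as a per-application limit l ~ U[0.1, 0.3] interpreted as
a scale fraction (scale ∈ [1−l, 1+l]) and as radians (rotation ∈ [−l, +l],
at most about ±17°); the unit is genuinely ambiguous, so the reading is
isolated in one function (`augment._affine`) and documented here.

## Evaluation

COCO conventions throughout: 101-point interpolated AP at IoU thresholds
0.50:0.05:0.95 (AP50, AP75, mean AP), average recall as the mean over
thresholds of recall at the 100-detections-per-image cap, and size classes
at 32²/96² pixel-area bounds with instance area = mask area.  The
large-object variants treat out-of-range ground truths as ignore regions
exactly as the COCO protocol does (a detection matched to an ignored ground
truth is neither TP nor FP).  The evaluator reads and writes COCO JSON with
run-length-encoded masks in both the uncompressed counts-list dialect and
the compressed LEB128-style string dialect.  FPS is wall-clock single-image
inference after warmup discard; it is hardware-dependent and reported for
orientation only.

## Synthetic scenes

The generator emulates the *statistical hard cases* of group-housed pig
footage rather than its appearance: elongated ellipse-union bodies with a
head lobe and low-frequency boundary wobble, clustered so bodies touch and
occlude (scenes are composited back-to-front and ground truth records the
visible parts, matching COCO practice), optional fence-like bars that cut
instances into pieces, and a night variant (brightness collapse,
desaturation, seeded sensor noise).  Every scene is a pure function of its
seed.  What passing tests on these scenes shows: the geometry pipeline —
assignment, loss plumbing, mask assembly, occlusion-aware ground truth,
evaluation — is correct, and the model can fit multi-instance overlapping
scenes.  What they do not show: performance on real animals, textures, or
lighting; no claim about real-data accuracy follows from the desk-scale
numbers.

## Known limitations

- The ResNet-50/101 variants are provided for architecture parity and
  forward-pass testing; training them on CPU at full frame size is out of
  desk-scale reach.
- Backbones omit batch normalization; at full scale this would need to be
  revisited.
- The attention slot accepts external plug-in modules, but only PSA ships.
- FPS numbers from the numpy engine are not comparable to GPU framework
  implementations.
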