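# Methods

## Model

The classifier is a pipeline of four stages:

1. **Backbone.** Any feature extractor satisfying the contract *image in,
   h′×w′×d feature map out* attaches here. The bundled `TinyBackbone`
   (conv3×3 → ReLU → maxpool2, twice; 8 and 16 channels by default) is a
   deliberate desk-scale extractor: large pretrained backbones plug in
   through the same interface but are out of scope for the tests.
2. **Soft-attention module.** The incoming map passes a ReLU, then splits:
   one path is 2×2 max-pooled directly, the other runs the soft-attention
   layer and is then pooled; both are concatenated (d + 2d = 3d channels),
   followed by ReLU and dropout p = 0.5 (training only).
   The attention layer computes K score maps with a same-padded
   convolution, softmax-normalizes each map *jointly over the h·w spatial
   positions* (so each map is a distribution over image locations, not over
   maps), sums them into α, and emits concat(t, γ·t⊙α). γ is learnable,
   initialized to 0.01 so the attended branch starts near zero and grows
   only if useful.
3. **Metadata head (optional).** Sex (3 levels incl. `unknown`), site
   (schema list + `unknown`) one-hot; age divided by a fixed 100-year scale
   plus a missing-indicator bit (missing age → slot 0, bit 1). The encoding
   is split-independent by construction (no data-driven statistics). A
   single linear dense layer (default 4096 units) maps it to a feature
   vector concatenated after the flattened image features.
4. **Classifier.** One dense layer and a softmax over the C classes.

### Numerical and design choices

* **K = 16 attention maps** by default (configurable; the studies use 4 to
  match their small feature maps). Kernel 3×3, same-padded.
* **Edge-filled padding** in the attention convolution: with zero padding a
  constant feature map would produce border-depressed scores; edge
  (replicate) padding preserves the identity *constant input → exactly
  uniform attention*, which the tests assert.
* **Softmax stability** by max-subtraction; attention maps sum to 1 within
  1e-6, α to K within 1e-5.
* **Loss clipping**: predicted probabilities are clipped to [1e-7, 1]
  before the log. The plain global 1/N normalization is used; no per-batch
  renormalization by the summed weights.
* **Weights from the training split only**, never the full dataset, to
  avoid leakage; a class absent from the training split is a hard error
  when weighting is enabled.
* **Split rounding**: train gets floor(n·f_train), the remainder goes to
  validation. Plain shuffled splitting is the default; a stratified option
  exists because an unstratified split can leave a rare class with zero
  validation members.
* **Argmax ties** break toward the lowest class index.
* **Division-by-zero metrics** report 0 and set a warning flag.
* **F1** is the harmonic mean of precision and recall. A variant that adds
  TN to the denominator — printed by some reports — is available behind
  `f1_includes_tn=True` but is not the default, since every comparative use
  of F1 presumes the standard form.
* **Balanced accuracy** averages per-class (sensitivity+specificity)/2.
* All arrays are float64; every layer's backward pass is validated against
  central finite differences (1e-4 relative or better).

## Optimization schedule

Adam with learning rate 0.001 and epsilon 0.1 (a deliberately large
epsilon that damps the per-parameter rescaling, making the update scale
with the gradient), batch size 32, up to 250 epochs. The learning rate is
multiplied by 0.2 when validation accuracy has not improved for
`lr_patience` epochs, floored at 1e-7. Early stopping fires after 25
non-improving epochs (so a frozen model trains exactly patience+1 epochs)
and restores the best-validation-accuracy weights. Augmentation: rotation
±180°, width/height shift ±0.1, zoom ±0.1, horizontal+vertical flips,
reflect fill, applied on the fly per batch.

## Synthetic data generator

Each image is a noisy skin-tone background plus one elliptical lesion blob
whose mean color, semi-axes and border irregularity (low-order radial
harmonics) are drawn from per-class ranges; classes are separable by
construction but overlap, so the Bayes error is positive. Metadata mimics
archive structure: ages from class-shifted normals rounded to 5-year bins,
sites from per-class preference lists, any field missing with a
configurable rate (default 0.05), kept as explicit `unknown` levels. The
default class counts mirror the HAM10000 ratios scaled by 0.1
(33/51/110/12/111/670/14), preserving the ~58:1 extreme imbalance at a
size a CPU can train on.

What the generator does **not** emulate: hair, rulers, gel bubbles,
vignetting, multi-lesion frames, site-dependent appearance, or the
intra-class texture diversity of real dermoscopy. Passing the directional
studies therefore shows that the *mechanisms* (weighting, fusion,
attention) behave as designed under controlled imbalance and
class-correlated metadata — not that any particular accuracy transfers to
real archives.

## The two directional studies

Both use a fixed-budget, constant-learning-rate protocol: early stopping,
best-weight restoration and the LR plateau schedule all monitor raw
validation accuracy, which on imbalanced data systematically favours
majority-biased models — a balanced-loss run trades accuracy for minority
recall and would be rolled back to its first epoch or frozen early.  The
studies therefore train every configuration for the same fixed number of
epochs at the base learning rate and compare final weights; the schedule
machinery itself is exercised by its own contract tests.

* **Imbalance mitigation.** Three-class sets with counts (600, 60, 20),
  24×24 images, lesion colors overlapping between neighbouring classes.
  For each seed, one model per weighting scheme (`none`, `original`,
  `balanced`) trains on a stratified 80/20 split for 200 epochs and is
  scored by macro recall on an independently drawn test set with the same
  class distribution (an independent draw gives 20 test samples of the
  rarest class instead of the 4 a validation split would hold). Unweighted
  training collapses onto the majority class (macro recall ≈ 1/3). The
  inverse-frequency scheme recovers the minorities quickly — its weights
  are C× larger, which with the scale-sensitive optimizer acts like a
  larger step — but its very large minority weights (34 on 16 training
  samples) make late training unstable and its test recall decays, while
  the balanced scheme converges more slowly and keeps improving; by the
  end of the budget the seed-averaged ordering none ≤ original ≤ balanced
  holds. 200 epochs is the point where the balanced runs have saturated.
* **Metadata benefit.** Balanced three-class sets (120 per class) whose
  lesion appearance barely separates the classes while mean ages are 20 /
  50 / 80 (sd 6). The same model trains 40 epochs with and without the
  metadata branch (64-unit head here; the 4096 default is the full-scale
  architecture and would be overparameterized on 288 training images); the
  comparison is best validation accuracy. The fused model exploits the age
  slot; the image-only model cannot.

Problem sizes (image geometry, channel widths, epoch budgets, 5 seeds) are
desk-scale choices: large enough for the contrasts to be stable across
seeds, small enough to run on one CPU in minutes.

## Known limitations

* The numpy implementation is single-threaded apart from BLAS matmuls and
  is meant for correctness and small studies, not throughput.
* The attention kernel spans the full channel depth with a 3×3 spatial
  extent; whole-map receptive fields would lock the layer to one input
  size and are not provided.
* γ is a single scalar for the whole layer, not per-map.
* The scaled attention branch is concatenated to t (not substituted), so
  the module output always doubles the channel count before pooling.
* No focal loss, label smoothing, imputation models, or calibration
  diagnostics.
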