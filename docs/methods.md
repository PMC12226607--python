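# Methods

## Problem setting

`replayseg` implements class-incremental semantic segmentation (CISS) under
a *binary-annotation* regime: every training image carries a pixel mask for
exactly one "most prominent" structure, other visible structures are
unlabeled, and new classes arrive on *disjoint* images in later steps. This
is the annotation convention of surgical anatomy datasets such as the
Dresden Surgical Anatomy Dataset, where incremental data are new patient
images rather than re-annotated old ones, and old images cannot be retained
for privacy reasons. The central difficulty is catastrophic forgetting:
fine-tuning on a new class set collapses performance on everything learned
before.

Training is organised into T+1 steps. Step 0 trains a segmenter M^0 on the
first class set with class-frequency-weighted cross-entropy, and trains an
unconditional denoising diffusion model on the same images. Each
incremental step t freezes M^{t-1}, expands the classification head for the
new classes, and optimises

    L_overall = L_Seg + L_KD + L_CL

on batches that mix the step's real images with diffusion-generated
*replay* images (generative replay stands in for the inaccessible old
data). At step 0 only L_Seg applies.

## Components

**Diffusion generator.** A standard DDPM with a linear variance schedule
β_s from 1e-4 to 0.02 (the original-DDPM convention; the source method
names only "a variance schedule"), ᾱ_s = ∏(1-β_s), reverse-step standard
deviation σ_s = √β_s with σ_1 = 0 so the final reverse step is
deterministic. Training minimises the mean over elements of
‖ε − ε_θ(√ᾱ_s x₀ + √(1−ᾱ_s) ε, s)‖²; the mean-over-elements reduction makes
the objective batch-size invariant. Sampling is plain ancestral sampling
from x_S ~ N(0, I). The noise predictor is a small two-level U-Net-style
encoder–decoder with a sinusoidal step embedding. The generator is trained
once on step-0 images and frozen; the replay set is generated once and
shared across incremental steps (a config flag allows regeneration).

**Segmenter.** A compact encoder–decoder: three 3×3 convolutions with one
2× pooling, a context block of two dilation-2 convolutions (standing in for
atrous spatial pyramid pooling at this scale), a decoder convolution after
2× upsampling, and a 1×1 classification head with one channel per known
class plus background. The output contract — logits, the ordered embedding
list L = (encoder feature, context output, logits), and a pooled encoder
feature z — is backbone-agnostic, so a larger backbone can be slotted in
without touching the losses or the trainer. Head expansion appends new
output channels initialised at scale 1e-3 and leaves old-channel parameters
bit-identical.

**Distillation (L_KD).** A layer-weighted sum of Euclidean distances
between the frozen and current models' embeddings, ω_l = 1 by default, with
the logits layer compared only on the channels the previous model knows.
The public `kd_loss` is the plain Euclidean form; inside the trainer each
layer's distance is divided by √(element count) (an RMS distance) and
averaged over the batch. Without this normalisation the distillation
gradient of a whole feature map dwarfs the cross-entropy gradient at this
model scale and the network cannot learn new classes at all. A config
switch selects the squared distance instead.

**Contrastive term (L_CL).** Pooled features are projected by a two-layer
head to 64 dimensions and L2-normalised (so dot products are cosines — a
stabilisation choice; the loss itself uses raw dot products of the
projections). For each real image the positive pair is its feature under
the current and previous models; the negatives are the current-model
feature of the real image against a replay image's features under both
models. Each real image is paired with one replay image drawn uniformly
from the replay portion of its batch; other real images are *not* used as
negatives. Temperature τ = 0.1. The batch value is the per-pair mean.

**Pseudo-labels.** For both real and replay images, the frozen previous
model's argmax prediction is kept wherever its softmax confidence reaches
0.7; ground truth (present only on real images) takes precedence inside the
annotated mask; all remaining pixels receive the ignore id (255) rather
than background, so uncertain regions are excluded from the loss.

**Weighted cross-entropy (L_Seg).** Inverse-pixel-frequency class weights
with one pixel of additive smoothing, normalised to mean 1 over the classes
present in the step's real data; a class absent from the data (old classes
at an incremental step) receives the maximum computed weight. The loss is
the mean over non-ignored pixels of weight × negative log-softmax.

## Synthetic study conditions

The scene generator emulates the binary-annotation regime at desk scale:
K = 5 classes, 32×32 RGB images in [-1, 1], 60 images per class, 70/10/20
train/val/test split per class, incremental split {1,2,3} → {4,5} (the
analogue of a 7–4 split). Each scene is a low-frequency noise background
with 1–2 textured superellipse blobs of the designated class (covered by
the binary mask, foreground fraction bounded in [0.02, 0.5]) and 0–2
unannotated distractor blobs of other classes — the distractors reproduce
the co-visible unlabeled structures that make pseudo-labeling both
necessary and possible. Classes are distinguished by evenly spaced hues, so
the benchmark is learnable: an offline segmenter trained on all five
classes reaches mean Dice ≥ 0.7 (checked in the test suite).

What the generator does *not* model: laparoscope optics, specularities,
smoke, occlusion, anatomical shape statistics, inter-patient appearance
variation, or any correlation structure between co-visible classes. Passing
the benchmark therefore demonstrates that the incremental machinery
(replay, distillation, contrast, pseudo-labels) works as designed, not that
it would reach any particular accuracy on real surgical imagery.

## Numerical and scale choices

Desk-scale defaults, chosen once for 1-CPU runs (the published experiments
use 256×256 crops, ResNet-101/ViT backbones, S = 1000 diffusion steps,
N = 1000 replay images, 50 epochs per step on GPUs):

| knob | desk default | full-scale reference |
|---|---|---|
| image size | 32×32 | 256×256 |
| diffusion steps S | 60 | 1000 |
| diffusion training | AdamW, lr 2e-3, 50 epochs, width 24 | AdamW, lr 1e-4, 150 epochs |
| replay set N | 64 | 1000 |
| segmenter optimiser | SGD momentum 0.9, lr 1e-2 | SGD, lr 1e-2 |
| epochs | 24 initial / 16 per step | 50 per step |
| batch size | 16 (½ replay at t>0) | 16 |

Further numerical choices: global gradient-norm clipping at 1.0 (without it
SGD at lr 1e-2 diverges on the joint objective at this scale); argmax ties
break toward the lowest channel index (background first); Dice is 1.0 when
both masks are empty and 0.0 when exactly one is; per-class Dice is
evaluated only on test images annotated with that class and averaged over
images (the one-class-per-image structure leaves no pixel-pooled
alternative); group summaries use the population (N-divisor) standard
deviation across classes, switchable to the sample deviation; all
randomness descends from one master seed through `numpy.random.SeedSequence`
spawning (documented sub-seed paths per step/purpose), and replay images get
per-image derived seeds so a replay set is reproducible image by image.

## Known limitations

* New-class acquisition in the distillation arms is conservative at desk
  scale: with ω_l = 1 on all three layers the plain-norm distillation pulls
  hard toward the frozen model, and new-class Dice stays well below what
  plain fine-tuning reaches. The squared-distance switch and per-layer
  weights are the knobs to trade stability for plasticity.
* The replay images from the tiny DDPM are blurry at 32×32; they carry
  enough class-specific colour/shape signal for pseudo-labeling, but their
  per-class coverage is uneven.
* The confidence threshold (0.7) is a fixed scalar; no calibration is
  attempted.
* Boundary refinement, CRF-style post-processing and test-time augmentation
  are out of scope.
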