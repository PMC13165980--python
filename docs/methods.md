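# Methods

## Model

The classifier is a *local-classifier-per-node* decomposition of a
K-way image classification problem over a two-level label taxonomy:
named groups (default: Benign = {ACK, NEV, SEK}, Malignant = {MEL, BCC,
SCC}) partition the leaf classes. The assembled tree makes one binary
decision at the root (group vs group), then, inside the reached group,
peels one class at a time (one-vs-rest) until two classes remain and a
final pairwise decision is made. For the default six-class taxonomy
this gives five decision nodes; an image is routed from the root by
taking the higher-scoring branch at each node (argmax of the two
softmax scores; exact ties go to the positive branch — the threshold is
a design choice, as the decomposition itself does not fix one).

Candidate models for every node are compared by the recall-first
cascade on unrounded values: recall, then F1, then precision, then
accuracy; a full four-way tie falls back to registration order (made
explicit so selection is a total, reproducible order). For binary
tasks "recall" is the positive class's recall, where the positive class
is the first-named class of the task (matching how benchmark tables
report binary rows); multi-class candidates compare macro recall.
Peel order within a group is chosen the same way: the class whose best
one-vs-rest candidate wins the cascade is peeled first.

## Data preparation

Images are resized directly to a square model input (default
224×224×3, bilinear, no aspect preservation — the fixed input contract
makes this the simplest defensible policy). A test fraction (default
20%, rounded half-up) of the *original* images is reserved before any
augmentation; splitting is image-level by default, with an optional
patient-level mode that moves whole patients to one side. Every
training class is then expanded to exactly `target_per_class` images
(default 3500) by repeatedly augmenting that class's originals in
round-robin order; a class already at the target passes through, and a
class above it is a configuration error (the pipeline never
downsamples). One augmentation draw is: scale factor uniform in
[0.80, 1.10]; independent horizontal and vertical reflection with
probability 0.5 each; centered placement on a zero-filled canvas of the
model input size (center crop on overflow). Order of operations
(scale → reflect → pad/crop), reflection axes, and centered placement
are design choices documented here because the transformation family
alone does not determine them.

Leakage checking is automated: duplicate image ids across splits,
pixel-identical content (SHA-1 of the pixel buffer) and shared patient
ids are reported. Under image-level splitting a shared patient is
reported but not fatal; under patient-level splitting it is an error.

## Backbones and training

The training configuration is shared by all backbones and tasks: Adam
with learning rate 1e-3, decay factors 0.9/0.999, epsilon 1e-8, L2
regularization 1e-4 folded into the gradient, mini-batches reshuffled
every epoch, periodic validation every 10 iterations, no early
stopping, optional per-epoch checkpoints. Two presets reflect the two
stated protocol variants — `table1` (batch 40, 300 epochs) and
`section25` (batch 20, 50 epochs) — plus a `tiny` preset (batch 16,
10 epochs) for desk-scale runs. The loss is cross-entropy (the standard
classification objective; the protocol names none). No layers are
frozen. Gradient clipping is disabled.

The working backbone is `tiny_test_cnn`, a small convolutional network
implemented in numpy with hand-written backpropagation: two 3×3
convolution → batch-norm → ReLU stages with 2×2 max-pooling after the
first, global average pooling, and a linear head. Batch normalization
uses batch statistics during training and running statistics at
inference; it is what lets Adam at lr 1e-3 train stably on small
batches (without it, optimization on the synthetic tasks oscillates
between majority-class collapse and sporadic fits). Weights use He
initialization from a seeded generator; training is bit-deterministic
given the seed on a fixed BLAS (documented as a contract, not enforced
across hardware). Working precision is float32; float64 is available
and used for gradient-accuracy studies. The four ImageNet-scale
architectures (MobileNetV2, EfficientNet-B0, ResNet-18, ResNet-50) are
registered by name so enumeration and selection handle them, but their
builders require the optional `torch` extra; without it they raise a
clear error. Pretraining for `tiny_test_cnn` does not exist; asking for
it warns and falls back to seeded random initialization.

Node models are trained on the full training pool relabeled for the
node's task: all classes reach the root, only a group's classes reach
its inner nodes. Binary class order is always `[positive, negative]`.

## Metrics

All seven metrics are computed from one-vs-rest TP/TN/FP/FN reductions
of the K×K confusion matrix, on unrounded ratios; macro values are
unweighted class means. Display rounding is half-away-from-zero at two
decimals and is applied only at presentation. Zero-denominator ratios
are defined as 0 with a logged warning — conservative under
recall-first selection, and the degenerate case (an empty class row)
warns rather than raises. Useful identities hold exactly: macro
balanced accuracy equals (macro recall + macro specificity)/2; for K=2
one class's recall is the other's specificity; per-class G-mean never
exceeds per-class balanced accuracy (AM–GM).

## Grad-CAM

Channel weights are the globally averaged gradients of the target
class's *pre-softmax* score with respect to the chosen feature layer's
maps; the localization map is the ReLU-rectified weighted sum,
upsampled bilinearly to the input size. Rendering normalizes by the map
maximum (an all-zero map renders uniformly blue) and overlays the jet
colormap at alpha 0.5; per-image normalization is a rendering choice —
raw maps are returned unnormalized. The default feature layer is the
last convolutional feature map before pooling (`relu2` for the tiny
CNN), overridable by layer name.

## Synthetic data generator

The generator emulates the one structural property the hierarchy
exploits: within-group classes look more alike than across-group
classes. Each class is an irregular ellipse (radius fraction, border
lobes, optional sinusoidal texture) filled with an HSV color on a
skin-tone background plus i.i.d. Gaussian channel noise (sd 45).
Benign hues occupy a warm band (20–40°), malignant a cool band
(200–224°): a ~160° separation that makes the root split easy, while
within-group discrimination rides on hue offsets of 10–12°, lightness
gaps of ≤ 0.14 and shape/texture differences. These amplitudes were
calibrated once so that a 5-epoch tiny-CNN run separates the groups
well but leaves within-group errors — the evaluation surface needs both
successes and mistakes. Patient ids are assigned in runs of 1–3 images
so patient-level splitting is exercised. Default image size is 64 px
(32 px in most unit tests); per-class counts of the imbalanced preset
decay from 100 (NEV) to 17 (SCC), max/min ratio ≈ 5.9, echoing the
NEV-dominance of public lesion collections.

What the generator does **not** model: dermoscopic artifacts (hair,
rulers, gel bubbles), illumination gradients, camera noise
correlations, intra-class morphology families, or any real lesion
appearance. Passing tests on synthetic data therefore demonstrate the
correctness and the relative behavior of the pipeline (hierarchy vs
flat under matched budgets), not clinical performance.

## Desk-scale replication

`hierarchy_vs_flat(seed)` is the package's standard desk-scale
experiment: 72 synthetic images per class at 64 px, an 80/20 split, one
tiny CNN per decision node and one flat six-way tiny CNN, all trained
10 epochs at batch 16, evaluated on the shared test side. Across seeds
the assembled hierarchy's macro recall exceeds the flat model's (the
acceptance suite averages five seeds); single seeds can go either way,
which is why the claim is asserted as a seed-averaged inequality. The
problem sizes are the package's chosen desk-scale study conditions —
large enough for the effect to be stable, small enough to run on one
CPU core in minutes.

## Numerical choices and edge cases

- Split sizes: test count is round-half-up of fraction × N, clamped to
  leave both sides nonempty.
- Balancing determinism: each class uses an independent generator
  seeded by (seed, class index); added copies cycle the class's
  originals from the first.
- Softmax is computed with max-subtraction; probabilities are clipped
  at 1e-12 inside the loss.
- Tie in routing scores takes the positive branch; tie in selection
  falls to earlier registration.
- Worked-example assertions use only published table cells whose
  recomputation is not a decimal midpoint, since midpoints are
  sensitive to the rounding convention of the source.

## Known limitations

- Without the optional `torch` extra the four large backbones cannot be
  built, only enumerated and selected over; the numpy CNN is the sole
  trainable backbone and is far below state-of-the-art capacity.
- The taxonomy is restricted to two levels (root groups + leaves) and
  exactly two groups at the root.
- No probability calibration across nodes, no soft routing, no
  rejection option, no ROC/AUC.
- Determinism across BLAS implementations/hardware is not guaranteed.
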