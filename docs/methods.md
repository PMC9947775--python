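# Methods

## Model

The segmenter is a two-class (brain / non-brain) encoder–decoder over
"data blocks": stacks of three consecutive slices of an isotropically
resampled, min–max-normalized volume, labeled by the middle slice's mask.
Five encoder stages (two 3D, then — after folding depth into batch — three
2D) halve the in-plane resolution four times; four decoder stages (two 2D,
then — after unfolding depth — two 3D) restore it, with pre-pooling encoder
features concatenated at every matching scale. The characteristic element
is the *hybrid* skip: the second 3D encoder's pre-pooling output
(`N×32×3×128×128` at full width/size) is channel-concatenated with the
restored-depth decoder features of the same shape, giving a 64-channel 3D
tensor; the published shapes force concatenation rather than addition. All
convolutions are 3×3(×3), stride 1, padding 1, each followed by batch
normalization (eval mode uses running statistics) and ReLU; upsampling is by
transposed convolution (2D 4×4 stride 2; 3D 3×4×4 stride (1,2,2), which
preserves the depth of 3) followed by ReLU without normalization; biases
are enabled everywhere. The output layer defaults to the stage table's
3×3×3 convolution, with the 1×1×1 reading available via
`HCNetConfig(head_kernel="1x1x1")`. Softmax normalizes the two class
channels per voxel.

Under the default widths (16, 32, 64, 128, 256) the network has 2,584,898
trainable parameters (2,584,066 with the 1×1×1 head); the count is
independent of cube size.

### Assumptions and conventions

* Grid axes 0/1/2 of the cube stand in for sagittal/coronal/axial; no
  anatomical reorientation is attempted, and none is needed because the
  tri-planar scheme is symmetric in the axes.
* Depth is fixed at 3. `to_4d` stacks depth into batch as `n*3 + d`
  (record depth, swap channel/depth, split along batch, splice along
  depth); `to_5d` is its exact inverse — verified bitwise in the tests.
* H = W = cube size must be divisible by 16 (four 2× poolings).

## Preprocessing and geometry

One trilinear resampling maps the native grid onto a size³ cube
(default 256) with edge-aligned sampling, so resampling a grid onto itself
is the identity; output spacing is `native_spacing × native_shape / size`,
preserving physical extent per axis. The single common grid is what makes
the three per-axis probability maps commensurable for fusion. Masks are
always moved by nearest-neighbour lookup (both directions), never
interpolated, so they stay exactly {0, 1}. Intensity normalization is
min–max to [0, 1]; a constant volume maps to zeros with a warning rather
than an error, keeping batch pipelines total.

## Training

Loss is the mean binary cross-entropy of the brain-class probability on the
**middle output slice only** — the only slice with a label; probabilities
are clamped to [1e-7, 1 − 1e-7] inside the log. The gradient is taken
through the softmax analytically ((p − y)/n on the middle slice, zero
elsewhere). The optimizer is Adam at a constant learning rate — the
community default for this architecture class — with defaults lr 1e-4,
batch 20, 50 epochs; a scheduler can be plugged in around the loop if
needed. Dataset order is deterministic (volume-major, axis, center) and
shuffled per epoch from the config seed; with a fixed seed the loss history
reproduces exactly. Validation Dice is the micro-averaged middle-slice Dice
over validation blocks (confusion counts pooled); the best-validation state
is kept. Volume-wise Dice after full tri-axis fusion is what the acceptance
suite measures on held-out phantoms, so both slice-wise and volume-wise
views are exercised. Non-finite loss aborts with a diagnostic.

## Inference and fusion

Block centers cover slices 2..N−1; the two boundary slices take the nearest
block's outer output slice (the network does predict all three slices), so
every slice is written exactly once per axis. Because the loss constrains
only the middle output slice, those outer slices are weakly trained, and a
single-axis mask can show artefacts on its two boundary slices; each axis's
boundary slices are interior slices of the other two axes, so the
three-axis mean suppresses exactly this error mode — on phantom cohorts the
fused Dice typically exceeds every single-axis Dice by a wide margin. The merge rule for the three
per-axis maps is an unweighted voxel-wise mean — the simplest symmetric
choice; majority vote is available (`rule="vote"`). Binarization uses
threshold 0.5 with ≥ tie-breaking, equivalent to two-class argmax. The
thresholded cube mask is mapped to native space by nearest neighbour; no
connected-component or hole-filling post-processing is applied by default.

## Phantom generator

Each phantom is: a bright ellipsoidal brain whose boundary is modulated by
a smooth random field (the mask is exactly this support — labels carry no
noise), a hollow shell of intermediate intensity (skull/scalp), two bright
anterior spheres outside the brain (eyes in adipose tissue), a
multiplicative smooth bias field, and additive Gaussian noise, on an
anisotropic default spacing of 0.60×1.20×0.60 mm. Cohort generation jitters
geometry (±10% semi-axes), tissue contrasts, bias amplitude, and noise
(0.01–0.05 SD, a five-fold SNR spread emulating different field strengths)
under one master seed. What the phantom does **not** model: cortical
folding, MR physics (k-space artefacts, B0/B1 inhomogeneity beyond a smooth
bias), partial-volume mixtures, and real skull topology. Passing the
learnability checks therefore demonstrates that the pipeline's geometry,
training, and fusion machinery are correct and learnable — not that the
default configuration reaches any particular accuracy on real scans.

## Numerical choices

* All tensors float32 in production; float64 is configurable and used by
  the finite-difference gradient checks.
* Convolutions are computed as one batched GEMM per kernel offset; the
  transposed convolution is the exact adjoint (verified by an inner-product
  identity test), so forward/backward pairs are consistent to rounding.
* Max-pooling routes gradients to the arg-max element (first occurrence on
  exact ties).
* Batch-norm eps 1e-5, momentum 0.1, unbiased running variance.
* Weight init: He-normal scaled by fan-in from the model seed; zero biases.
* Degenerate metric denominators (empty truth *and* prediction) return
  perfect scores with a warning; VOE returns 0.

## Desk-scale profile

CPU-scale experiments in the test suite use cube 64, channel widths
(4, 8, 16, 32, 64), Adam at 1e-3, batch 20 — a quarter-width network; with
~450 optimizer steps over 16 phantom volumes (two epochs) held-out fused
Dice exceeds 0.9, and a single volume is memorized within 20 epochs. The
reduced widths and the matching higher learning rate are the package's
standard small-model profile; the full-width 256³ configuration uses the
stock hyperparameters (lr 1e-4, 50 epochs).

## Known limitations

* The full-width 256³ configuration trains impractically slowly on a single
  CPU; the implementation is intended for methodological study and
  desk-scale experimentation, not production GPU throughput.
* No orientation inference: volumes are processed in grid axes as stored.
* No post-processing of masks (largest-component selection etc.); stray
  false-positive islands are possible on hard inputs.
* The phantom's simplicity means hyperparameter choices validated on it do
  not transfer to real data without re-tuning.
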