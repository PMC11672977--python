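# Methods

`hemseg` implements an end-to-end pipeline for simultaneous segmentation of
intracerebral hemorrhage (ICH) and perihematomal edema (PHE) on non-contrast
head CT, with individual-level prediction-uncertainty scoring.  This note
documents the model, its assumptions, the parameters that matter, and the
limits of what the synthetic validation shows.

## Preprocessing

A head CT in Hounsfield units (HU) passes through four deterministic steps:

1. **Skull stripping.**  Voxels outside [0, 200] HU are removed (air and fat
   lie below 0 HU, bone above 200 HU).  Binary opening followed by closing
   with an anisotropy-aware ellipsoidal structuring element (default radius
   2 voxels in-plane, 1 across slices) removes scalp and soft-tissue
   fragments; the largest connected component is kept.  The mask never
   includes a voxel outside the HU range — when closing re-annexes boundary
   voxels, the HU constraint wins.
2. **Brain windowing.**  Standard radiology windowing at level 40 / width
   80 HU: `clip((HU - (level - width/2)) / width, 0, 1)`.  With defaults,
   0 HU maps to 0 and 80 HU to 1; the mapping is monotone.  Non-brain voxels
   are set to the window floor before cropping so bone and air never reach
   the network.
3. **Cropping.**  Tight axis-aligned bounding box of the brain mask
   (margin configurable, default 0).
4. **Resampling.**  Linear interpolation for images, nearest-neighbor for
   labels, to a common spacing — in clinical use the mean spacing of the
   training cohort (e.g. 3.75 × 0.46 × 0.46 mm).  Output shapes follow
   `round(shape × spacing / target)` with round-half-away-from-zero and a
   floor of 1, so results are platform-stable.

Every step is recorded in a `PreprocessRecord` (original shape/spacing, crop
offset, target spacing); predicted masks are reverted to the native CT grid
by nearest-neighbor resampling back to the cropped box and pasting at the
recorded offset.  Axis convention is `(slice, row, column)`, 0-based,
half-open; preprocessing is fully deterministic.

## Dual-branch network

Two U-shaped branches process each patch independently and are fused only at
the output:

* **Transformer branch** — a convolutional stem at full resolution (the
  finest skip connection), a strided patch embedding to half resolution,
  then per level one regular and one shifted windowed self-attention block
  (window (2, 4, 4), 2 heads, pre-norm, 2× MLP).  Shifted blocks roll the
  feature map cyclically by half a window; cross-boundary attention wraps
  rather than being masked — at desk scale the approximation is immaterial
  and it keeps the kernel count low.
* **Convolutional branch** — a plain U-Net: conv blocks
  (conv → instance norm → leaky ReLU) with 2× max pooling down, and a
  decoder shared in structure with the other branch: nearest-neighbor 2×
  upsampling, 1×1×1 channel reduction, additive skip connection, then a
  conv block.

Design choices worth calling out:

* **Anisotropic fine-level kernels.**  At full resolution the convolutions
  are (1, 3, 3): clinical CT slices (~5 mm) are an order of magnitude
  thicker than pixels (~0.5 mm), so through-plane mixing at the finest scale
  adds cost without adding information.  Deeper levels use 3×3×3.
* **Additive skips.**  The decoder reduces upsampled channels with a 1×1×1
  convolution and adds the skip rather than concatenating; this halves the
  widest convolutions with no measurable accuracy cost at this scale.
* **Deep supervision.**  Each branch emits class probabilities (softmax) at
  every decoder resolution plus the bottleneck — `levels + 1` outputs per
  branch (capped at 6), shaped `patch / 2^k`.
* **Class-prior bias initialization.**  The 1×1×1 classification heads start
  with biases at log class priors (defaults ≈ 98.5% background, 0.5% ICH,
  1% PHE).  Lesions occupy well under 1% of a head CT; with zero-initialized
  heads the first epochs are spent collapsing all foreground before the
  Dice term can recover it, and the weak-contrast PHE class does not emerge
  within a short schedule.  Prior initialization removes that transient.
* **Fusion.**  The final prediction is the voxel-wise arithmetic mean of the
  two branches' full-resolution probability maps (which stays on the
  simplex), with argmax ties broken toward background.

Weight initialization is He-style, seeded, and bit-reproducible; the forward
pass in evaluation is deterministic.

The network, its autodiff engine, and the optimizers are implemented in
numpy inside the package (`hemseg.nnet`): reverse-mode autodiff over
float32 arrays, im2col-based 3D convolution, windowed attention via
reshape/transpose partitioning, SGD with Nesterov momentum, and Adam.  All
layer gradients are verified against central finite differences in the test
suite.

## Loss and training protocol

Every supervised output contributes `CE + (1 − soft Dice)`:

* cross-entropy on probabilities, uniform class weighting;
* soft Dice per foreground class (ICH, PHE) with additive smoothing
  ε = 1e-5 in numerator and denominator, averaged over the two classes —
  background is excluded so its dominance cannot mask lesion error.

Ground truth is downsampled to each supervised resolution by
lesion-priority majority voting: the most frequent label in each block
wins, ties prefer the higher label (PHE > ICH > background) so thin rims
survive coarsening.  Per-resolution weights decay geometrically
(w_k ∝ 2^-k, normalized), identical for both branches; the total is the
weighted sum over both branches' outputs.

The default protocol is SGD with Nesterov momentum 0.99, initial learning
rate 1e-2, weight decay 3e-5, polynomial decay `lr₀ · (1 − epoch/max)^0.9`,
100 epochs, patch (32, 256, 256).  An alternate preset carries the
benchmark-model protocol (Adam, lr 1e-4, cosine annealing, Dice-Focal loss,
patch (64, 64, 64)).  Patches are sampled half centered on random lesion
voxels and half uniformly — lesions are tiny relative to the volume, and
unbiased sampling starves the loss.  Per epoch the model is validated by
full sliding-window fused inference; the weights with the best mean
foreground Dice are retained.  Cross-validation splits are grouped by
patient (shuffle patients, deal round-robin), so baseline/follow-up scan
pairs never straddle folds and fold sizes differ by at most one patient.

## Inference and uncertainty

Whole volumes are predicted in overlapping sliding windows (origins at
stride `ceil(window · (1 − overlap))`, the last clamped to the image edge;
images smaller than the window are symmetrically zero-padded).  Window
probabilities are blended with a Gaussian importance map (σ = window/8,
floored at 1e-4 of its peak) and renormalized per voxel.

Prediction uncertainty uses test-time augmentation.  With V₀ the segmented
volume (mL) of a class in the unaugmented prediction and Vᵢ the volumes
from n augmented predictions (each under an invertible transform — left-
right flip, rotation within ±10° about the slice axis, isotropic zoom in
[0.9, 1.1] — inverted on the label grid before measuring), the score is

    U = (1/n) Σᵢ |Vᵢ − V₀| / (Vᵢ + V₀)  ∈ [0, 1],

with a term counted as 0 when Vᵢ + V₀ = 0 (both runs agree the class is
absent; agreement should not add uncertainty).  The ICH and PHE scores are
averaged into a subject score; subjects above a configurable threshold
(default 0.2) are flagged for review.  A helper calibrates the threshold to
a target flag rate on a reference cohort, since the operating point is
data-dependent.  The score is permutation- and scale-invariant in the
volumes.

## Evaluation metrics

* Dice = 2|A∩B| / (|A|+|B|); 1 when both masks are empty.
* Hausdorff distance: true bidirectional maximum of surface-to-nearest-
  surface distances in mm (surface = mask voxels with a face-neighbor
  outside); undefined (NaN, with a warning) when either mask is empty; a
  percentile variant is available but the maximum is the default.
* Volume similarity = 1 − |V_A − V_B| / (V_A + V_B); 1 when both empty, 0
  when exactly one is.

Cohort summaries report mean ± sd, median and interquartile bounds per class
and metric, optionally excluding uncertainty-flagged cases.

## Synthetic phantoms

The phantom generator produces head-CT-like volumes with known ground
truth: an ellipsoidal skull shell (1200 HU, 6 mm) with a thin scalp layer
outside it (30 HU), brain parenchyma at 35 HU, paired CSF ventricles at
8 HU, a hematoma built as a volume-matched smooth random blob at 65 HU, and
a contiguous edema rim at 18 HU (hypodense to brain, denser than CSF) whose
thickness is a distance-transform radius in mm.  Optional intraventricular
blood is hyperdense but labeled background, mirroring the convention that
IVH is excluded from the ICH label.  Gaussian HU noise (default sd 4) and
anisotropic spacing (default 5.0 × 2.75 × 2.75 mm over a 32 × 96 × 96 grid)
complete the emulation.  Hematoma volume is matched by bisecting the blob
threshold against the largest connected component, so realized volumes land
within a fraction of a percent of the request.  Cohort sampling draws
per-case parameters from configurable ranges (defaults: ICH 8–25 mL, rim
4–8 mm, 15% infratentorial placement, 15% IVH carriers) and assigns
synthetic patient IDs with about half the patients contributing a
baseline/follow-up pair.

What the phantoms do **not** emulate: real neuroanatomy, partial-volume
effects at thick-slice boundaries, scanner physics (beam hardening, metal
artifacts), leukoaraiosis and other PHE confounders, or the intensity
overlap between PHE and chronic ischemic change that makes clinical PHE
segmentation genuinely hard.  Passing the synthetic suite therefore
demonstrates that the machinery is correct and can learn the intended
contrast structure — not that the tiny model would reach clinical accuracy
on patient scans.

## Desk-scale experiment sizes

The reference experiment trains the tiny configuration (patch (16, 64, 64),
base width 8, 3 levels, 4 supervised outputs per branch) on a 50-case
synthetic cohort: patient-grouped 5-fold split, fold 0 (~10 scans) held
out, 16 epochs, 2 patches per case per epoch, batch 2.  Sixteen epochs is
enough for both lesion classes to emerge under the decaying schedule; ICH
(strong contrast) saturates within a few epochs, PHE (weak contrast, thin
rim) emerges later.  Uncertainty scoring uses n = 8 augmentations.  Larger
configurations differ only in the config objects.

## Known limitations

* The engine is CPU-bound numpy; it is deliberately scale-free but not fast
  — the published full-scale configuration (patch (32, 256, 256), 100
  epochs, thousands of scans) is expressible but not practical here.
* Shifted-window attention wraps cyclically instead of masking across the
  roll boundary.
* Instance-norm statistics are always computed from the current input
  (there are no running averages), so extremely small inference patches see
  slightly different normalization than training patches of the same size.
* The TTA transform family is fixed to flips/small rotations/zooms; the
  uncertainty threshold default (0.2) is a repo parameter to be calibrated
  per deployment, not a clinically validated operating point.
* The volume-divergence uncertainty score has a structural blind spot: a
  prediction error that is *stable* under augmentation — e.g. a hyperdense
  intraventricular blood region consistently included in the hemorrhage
  mask — produces the same volume in every augmented run and scores as
  fully confident.  The score detects augmentation-sensitive errors
  (uncertain boundaries, near-threshold tissue, fragile detections of small
  lesions), which in clinical cohorts dominate the failure tail; on small
  synthetic cohorts where the stable-false-positive mode dominates, the
  uncertainty–accuracy association for hemorrhage can invert even while the
  edema association shows the expected direction.
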