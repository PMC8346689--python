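# Methods

## The segmentation problem

`priorseg` segments a T1-weighted brain MRI into six tissue classes —
CSF (1), cortical gray matter (2), white matter (3), deep gray matter
(4), brainstem (5), cerebellum (6) — with 0 reserved for background.  The
difficulty on clinical material is twofold: acquisition heterogeneity
(contrast and resolution vary by scanner and sequence), and lesions that
distort signal without changing the underlying tissue class.  The
pipeline addresses both by feeding the network a *spatial prior*: a crude
subject-space segmentation obtained by warping a template's labels
through a fitted registration, supplied as a second input channel.

## Pipeline

For one subject: (optional) skull strip with a binary instance of the
same network → crop to the foreground bounding box → resample to an
isotropic cube (128 per axis at clinical scale; tests and the acceptance
script use 32) → z-score the intensities over the cropped volume → build
the prior on that same grid → network inference → background decision
rule → map the prediction back to the native grid.  The crop/resample
geometry is recorded in a `CropRecord` so the inverse mapping is exact:
the cube prediction is resampled to the crop shape and placed at the
recorded bounds, background elsewhere.

Label maps are never interpolated directly.  Every resampling of labels
(cube resampling, augmentation, warps) smooths each class indicator with
a small Gaussian, interpolates trilinearly, and takes the voxelwise
argmax, so no operation can invent a label code.

The fixed preprocessing order is crop → resample → z-score.  z-scoring
after the crop means statistics are computed over head voxels rather
than empty background; the alternative order changes only the affine
normalization constants.

## Network

A 3-D encoder–decoder with 4 downsampling and 4 upsampling blocks and
skip connections.  Downsampling uses stride-2 3×3×3 convolutions into
residual *context* modules (two 3×3×3 convolutions with channelwise
dropout, rate 0.3, between them).  Upsampling blocks are
nearest-neighbor ×2 upscale + 3×3×3 convolution, concatenation with the
skip, then a *localization* module (3×3×3 followed by 1×1×1
convolution).  Instance normalization and leaky ReLU (slope 0.01) follow
every 3×3×3 convolution; instance norm is the right choice because the
batch size is one volume.  The last three decoder levels feed linear
1×1×1 segmentation heads whose outputs are upsampled to the input shape
and summed before a single final activation (deep supervision by summed
side outputs).  Keeping the heads linear is a deliberate deviation from
"normalize after every convolution": normalizing a head's output would
rescale the logits being summed.

Two tissue head configurations, tied to the loss:

* **soft Dice** — 6 sigmoid channels, no background channel.  A voxel is
  assigned the argmax class, *unless* no channel exceeds 0.5, in which
  case it is background.  Ties break to the lowest channel index; the
  threshold is strict ("exceeds" = `> 0.5`).
* **CCE / WCCE** — 7 softmax channels with explicit background; the
  decision is a plain argmax and the 0.5 rule never applies.

The networks are implemented on a small NumPy reverse-mode autodiff
engine written for this package (`priorseg.nn.autograd`): convolutions
are evaluated as 27 shifted GEMMs over views of the padded volume, and
every operation's gradient is validated against central finite
differences in the test suite.  This keeps the package dependency-light
and fully deterministic on CPU; it is sized for the desk-scale grids
(16–64 cubes) used throughout.

## Losses

* Soft Dice: `1 − mean_c (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1e-5 in both
  numerator and denominator, an unweighted mean over the six tissue
  channels.  Background participates implicitly through the zero targets
  of the six channels.
* CCE: voxel-mean of `−Σ_c t_c log p_c`, probabilities clamped at 1e-7.
* WCCE: CCE with per-class weights `w_i = median(n_b) / median(n_i)`,
  where `n_b`, `n_i` are per-subject voxel counts of background and
  class *i* and the median is taken across the training set.  The
  background weight is 1 by construction; a class whose median count is
  zero is an error.

## Spatial prior

Subject → template registration in three stages: 6-dof rigid (centered
initialization), 12-dof affine initialized from the rigid result, then a
symmetric-forces demons deformable stage run coarse-to-fine (shrink 2
then 1) after histogram-matching the affinely resampled template to the
subject.  The rigid/affine similarity is normalized cross-correlation
with full sampling and fixed iteration budgets, so the whole chain is
deterministic.  Template labels are brought onto the subject grid with
the smoothed-label rule at σ = 0.2 voxels and an argmax that includes
background.  The engine behind the `TransformChain` interface is
SimpleITK; the contract (stage order, forward/inverse application,
serialization of the affine as a 4×4 matrix and the deformation as a
vector field) is this module's.

The prior enters the network as a single channel of label codes scaled
to [0, 1] and then standardized, so the prior and the z-scored T1 carry
comparable dynamic range.  (The channel count — two — is the design
constraint; the numeric encoding is this package's choice.)

The same warped labels double as the *registration-to-atlas baseline*
segmenter; on default phantoms it achieves an overall Dice around 0.70,
crude but informative, which is the regime the prior is meant for.

## Training

Adam from seeded random initialization, batch size 1, inner 90/10
subject-level split (drawn once, seeded) for plateau detection.  After
10 epochs without validation-loss improvement the learning rate halves;
training stops after 50 epochs without improvement; "improvement" means
strictly below the best loss minus 1e-5.  The checkpoint with the best
validation loss is kept.  Random-affine augmentation (rotation ≤10°,
scale ≤10%, translation ~4% of the field of view) is applied jointly to
all input channels and the target labels.

The default initial learning rate is 0.0005, appropriate for
clinical-scale training (hundreds of subjects at 128-cubes).  The
desk-scale experiments in the test suite and acceptance script use
0.002–0.005: at 32-cubes with <10 subjects, a few hundred optimization
steps are available in total and the plateau schedule never reaches
convergence at the clinical-scale rate.  The schedule semantics
themselves (factor 0.5 / patience 10 / stop 50) are unchanged and tested
directly on synthetic loss traces.

Transfer learning re-runs the same schedule from a pretrained
checkpoint, inheriting its loss/prior configuration.  The leave-one-out
protocol over *n* subjects trains *n* models: fold *i* holds out subject
*i*, validates on subject *i+1 (mod n)* (a fixed round-robin assignment),
and trains on the rest;
each subject is predicted exactly once by a model that never saw it.

## Evaluation

* Dice `2TP/(2TP+FP+FN)`; defined as 1.0 when both masks are empty.
* Volume similarity `1 − |V_X−V_Y|/(V_X+V_Y)`; location-blind; 1.0 when
  both are empty.
* HD95: *directed* (predicted → true) 95th percentile of per-voxel
  minimum Euclidean distances in mm, anisotropic spacing honored,
  linear-interpolation percentile.  A symmetric variant exists but is
  not the default; the directed form is the definition this package uses.
  Undefined (error) on empty masks.
* Intra-lesion accuracy: fraction of WM-lesion voxels predicted as
  label 3, and of GM-lesion voxels predicted as label 2 or 4.  Empty
  masks are reported as missing and excluded from cohort aggregates.
* Two-sample Z: `(x̄1−x̄2)/√(σ1²/n1+σ2²/n2)` with sample SDs (ddof 1);
  |Z| > 2.5 flags significance with the sign giving direction.
* External 10-class manual schemes are harmonized by condensing
  ventricles+CSF into CSF, relabeling WM hyperintensities as WM, and
  masking infarction/other voxels out of every metric via an exclusion
  mask (their tissue class is undefined).

All metrics are validated against brute-force oracles (exhaustive
pairwise distances, direct confusion counts) on random small masks.

## The phantom cohort

The generator emulates the statistical structure of a heterogeneous
clinical T1 cohort on a parametric geometry (no downloaded atlas):

* **Geometry** — nested ellipsoidal CSF / cortical-GM / WM shells;
  paired deep-gray nuclei (~4% of brain volume, the anatomical share of
  thalamus + basal ganglia) beside CSF ventricles; an inferior brainstem
  cylinder (~3%); a posterior cerebellum lobe.  The cortical shell is
  deliberately thin (a hard class) and the deep nuclei sit at low,
  controllable contrast against WM (`contrast_scale` multiplies the
  deep-GM-vs-WM intensity gap), reproducing the classic failure mode of
  intensity-driven segmentation.
* **Inter-subject variability** — a random *divergence-free* smooth warp
  (curl of a Gaussian-smoothed vector potential, SD 3 mm, 8 mm
  correlation length).  Divergence-free matters: a plain smoothed-noise
  field gave small structures absurd 3× volume variation, whereas real
  anatomy varies in shape far more than in local volume.  On top of the
  warp, a per-subject head pose (rotation ≤12° per axis, scale ≤8%),
  because clinical scans are not pose-normalized.
* **Intensity model** — per-tissue means in a T1-like ordering
  (WM > deep GM ≈ brainstem > cortical GM ≈ cerebellum > CSF) with 5%
  per-subject jitter (scanner variability), within-class smooth texture,
  a multiplicative exponential-polynomial bias field (10% amplitude) and
  additive Gaussian noise (SD 2 on a 0–100 intensity scale).
* **Lesions** — wobbly spheres (2–5 mm radius) placed wholly inside WM
  or the deep-gray nuclei, with a negative (T1-hypointense) intensity
  shift applied before bias and noise.  Ground-truth labels keep the
  underlying tissue class; the lesion masks are what intra-lesion
  accuracy scores.  The lesion size/intensity distributions are free
  parameters of the phantom, not estimates of any clinical dataset.

What the phantom does *not* emulate: MR physics (no sequence model, no
partial-volume mixtures beyond interpolation), real cortical folding,
multi-contrast acquisitions, or exogenous tissue (hemorrhage, tumor).
Passing phantom tests therefore demonstrates the pipeline's mechanics
and the direction of its design effects, not clinical accuracy.

## Desk-scale experiments and what they show

Problem sizes were chosen so the full suite runs on one CPU: 64-cube
native phantoms, 32-cube network grids, 8 base filters, cohorts of 7–12.

* **End-to-end run** — 8 training subjects, soft Dice + prior, random
  affine augmentation, 150 epochs at lr 0.002.  Held-out overall Dice
  ≈ 0.81 with every class above the registration-only baseline
  (≈ 0.70 overall), reproducing the qualitative ordering the method is
  built on.
* **Prior effect** — on low-contrast phantoms (`contrast_scale` 0.15)
  the deep-gray class is nearly invisible in the image; with a fixed
  small training budget (45 epochs, CCE head) the prior-augmented arm
  beats the image-only arm in deep-gray Dice across seeds.  On phantoms
  this is a sample/compute-efficiency effect: the prior is a function of
  the subject image and the template, so with unlimited desk-scale
  training the image-only network eventually closes the gap by learning
  the (phantom-simple) spatial relation between the deep nuclei and the
  visible ventricles.  Clinical anatomy and acquisition variability are
  far richer, which is why the advantage persists at scale there; the
  phantom experiment checks the direction under matched budgets.

## Numerical conventions and degenerate inputs

Voxel indices are 0-based, crop intervals half-open, and the NIfTI
affine is the sole source of world coordinates.  Cube resampling uses
the endpoint-aligned convention and updates the affine accordingly.
Constant volumes are rejected by `zscore` (no silent epsilon) and by
`register` (similarity undefined).  Empty foregrounds, empty masks in
HD95, label maps with codes outside their scheme, mismatched grids and
incompatible checkpoints all raise immediately with the offending item
named.  Exact probability ties resolve to the lowest channel index.
Displacement-field inversion uses fixed-point iteration, valid in the
small-deformation regime the generator produces.

## Known limitations

The NumPy engine is CPU-bound and sized for desk-scale grids; 128-cube
training at clinical scale would need hours per epoch.  The demons stage
under-recovers strongly rotational warps (visible as the crude prior —
acceptable here, since a crude prior is the operating regime).  The
phantom's cortical shell at 32-cubes is near the resolution limit, so
round-trip label fidelity at that cube size is bounded by interpolation
rather than by the method.
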