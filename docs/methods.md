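# Methods

## Problem and pipeline

`crestseg` segments the bony pelvis — the ilium, ischium and sacrum, with the
iliac crest as the clinically relevant part for vascularized bone grafts in
mandibular reconstruction — from CT volumes, and turns the segmentation into
a triangulated surface mesh ready for virtual surgical planning.

The pipeline is a coarse-to-fine cascade of two identical fully convolutional
3D U-Nets operating at different fixed grids:

1. **Stage 1 (localization).** The CT is intensity-normalized and resampled
   to `160 x 160 x 224` voxels (per-axis anisotropic scaling that preserves
   the physical field of view). The stage-1 network segments the bone in the
   full field of view; its binarized output defines a bounding box in native
   CT coordinates, expanded by a configurable margin (default 5% per axis).
2. **Stage 2 (refinement).** The native CT is cropped to that box and
   resampled to `256 x 144 x 144`, giving the second network a much higher
   relative resolution over the bone. Its binarized output, with the crop's
   origin and spacing attached, is the segmentation proper.
3. **Post-processing.** One layer of binary erosion (6-connected cross),
   Gaussian smoothing of the {0,1} field (sigma 1 voxel), and marching cubes
   at iso 0.5 produce the output mesh in patient millimetre coordinates.
   The erosion deliberately compensates the dilation built into the greedy
   training masks (below); disconnected fragments are kept, never discarded.

## Network and training

The U-Net has five resolution levels with two `3x3x3` convolutions each in
the encoder (ten in total) separated by four `2x2x2` max-poolings, feature
maps doubling at each level; the decoder has four `2x2x2` nearest-neighbour
up-samplings, each followed by two convolutions on the concatenation with the
skip connection, and a final `1x1x1` convolution with a sigmoid — nine
decoder convolutions. Activations are leaky ReLU (negative slope 0.01):
with batch-size-1 Dice training a loss spike can push a small network into
an all-dead-ReLU state from which the saturated sigmoid cannot recover, and
the leaky slope keeps a gradient path alive. Every hidden convolution is
followed by per-channel instance normalization (`instance_norm=True` by
default, with learned scale and shift) — the standard normalization for
batch-size-1 volumetric segmentation. Beyond conditioning, it bounds the
activation scale, which removes a failure mode observed in unnormalized
desk-scale runs: an over-segmentation phase produces a coherent "push all
logits down" Dice gradient, the unbounded activations let a few epochs of
that overshoot deep into sigmoid saturation, and training collapses
irrecoverably to all-background. The output convolution's bias is
initialized to the logit of the expected foreground fraction (default −2,
sigmoid ≈ 0.12), which suppresses the large early-training oscillation of
Dice-loss optimization that starts from an uninformed sigmoid. The net is
fully convolutional: any input divisible by 16 per axis works, and the
parameter count depends only on the configuration
(`unet.expected_param_count` gives the closed form).

Training minimizes the soft Dice loss `L = 1 - DS` with
`DS = (2 Σ p t + ε) / (Σ p + Σ t + ε)`, `ε = 1e-6` (stability on empty
targets), using Adam with batch size 1 and initial learning rate `5e-4`.
The learning rate is divided by 10 after 10 epochs without validation-loss
improvement (improvement = decrease by more than `1e-5`); training stops
after 30 epochs without improvement. The reduction counter restarts after
each reduction; the stop counter runs from the last improvement — that is
what allows a reduction at stagnation epoch 10, another at 20, and a stop at
30. No data augmentation is used. Whether the plateau criterion watches
training or validation loss was an open choice; validation loss is used.

Two robustness knobs wrap the schedule without changing its state machine.
First, the scheduler is fed a short running mean of the validation loss
(`val_smoothing_epochs`, default 3; 1 = raw): with a small validation set
the raw per-epoch loss is noisy enough — thin-shell Dice moves a lot under
sub-voxel boundary shifts — that one lucky epoch can set an unbeatable
best-so-far reference and freeze the learning rate during the early
transient. Best-weight selection still uses the raw per-epoch loss.
Second, optional global-norm gradient clipping (`clip_grad_norm`, default
off) is available against occasional huge single-sample Dice gradients.

Stage 2 is trained first from Glorot-uniform initial weights; stage 1 is
then initialized with the trained stage-2 weights (transfer across
resolutions is possible because the network is fully convolutional) and
fine-tuned end to end — the default freeze set is empty. Stage-2 training
crops use the ground-truth bounding box, since stage-1 predictions are
undefined while the stages are trained separately; the training crop margin
equals the inference ROI margin (5% per side) so the stage-2 input
statistics agree between training and prediction.

The network, including forward and backward passes and Adam, is implemented
in NumPy with numba-compiled direct convolution kernels (a pure-NumPy
windowed fallback exists). Gradients are validated against central finite
differences in the test suite.

## Training targets: greedy voxelization

Ground truth arrives as watertight surface meshes in patient mm. Training
masks are computed at native CT resolution with a *greedy* rasterization: a
voxel is foreground iff its box `centre ± spacing/2` has some extent inside
the mesh (interior or surface). Implementation: even-odd parity counting of
surface crossings along z columns for centre containment, plus an exact
(strict) triangle–box separating-axis test for all boundary voxels. The
strictness matters: a triangle merely touching a voxel face contributes zero
extent and is excluded, which makes exactly aligned solids rasterize to
exactly their voxel count. The greedy mask is a superset of the
centre-containment mask by construction and is dilated by roughly half a
voxel diagonal at the boundary; the post-processing erosion removes that bias
again. Masks are resampled to stage grids by trilinear interpolation
followed by a 0.5 threshold, which avoids the aliasing holes that
nearest-neighbour downsampling punches through thin cortical shells.

## Intensity handling

CT values are clipped to the full 12-bit range `[-1024, 3071]` HU and mapped
affinely to `[0, 1]`. The window is a package default, not a protocol value;
a narrower bone window was tried and did not improve phantom convergence.

## Evaluation metrics

All metrics compare triangulated surfaces (prediction vs ground truth),
because meshes are what surgical planning consumes:

* **DSC** — both meshes are voxelized by centre containment on a single
  shared grid covering their joint bounds (default pitch 0.5 mm,
  configurable) and `2|A∩B| / (|A|+|B|)` is computed. The shared grid makes
  the measure exactly symmetric; the pitch choice trades accuracy for time
  and the value converges as the pitch shrinks.
* **ASD** — area-weighted random samples are drawn on each surface
  (default 100,000 per surface, seeded); each sample's distance is the exact
  point-to-nearest-triangle distance to the opposing surface (Ericson's
  closest-point construction, pruned by a k-d tree over triangle centroids
  with a radius bound that guarantees exactness). The symmetric ASD is the
  mean over the pooled samples of both directions.
* **HD95** — the 95th percentile of the same pooled directed distances.
  "Symmetric 95% Hausdorff" is ambiguous between pooling and taking the max
  of two one-sided percentiles; pooled is the default, `how="max"` is
  available.

A brute-force O(N·M) all-pairs oracle (`directed_distances_bruteforce`)
backs the accelerated path in the tests.

## Transplant ROI

The transplant-relevant crest region is delimited by an oblique cutting
plane recorded relative to a reference bone: the anchor is stored as the
offset from the mesh's geometric centre divided componentwise by the
bounding-box half-extents; the normal is stored in absolute orientation.
Applying the ROI to a new bone reconstructs the absolute plane from that
bone's centre and half-extents and clips the mesh, keeping every fragment on
the crest side. Normalizing by half-extents (rather than centring alone)
makes the plane land at an anatomically comparable position on bones of
different size; a pure-translation mode (`mode="translate"`) is provided for
strict centre-relative placement. The geometric centre is the area-weighted
surface centroid — defined for any mesh including non-watertight
post-processing outputs; a volume-centroid option exists. Left and right
definitions are mirror images across the first (mid-sagittal) axis.

For a prediction/truth pair the absolute plane is always derived from the
*truth* mesh and reused for the prediction, so both are clipped over the
identical region.

## Synthetic phantoms

Real pelvis CTs with expert segmentations cannot be redistributed, so the
package ships a procedural phantom generator that emulates the geometry the
pipeline must handle: two mirrored thin-walled ellipsoidal shell caps
("iliac wings", opening caudally, with per-case radii, thickness, cut angle
and a small left/right asymmetry jitter) plus a central superquadric block
("sacrum"), posed with a small random rigid rotation inside volumes of
varying shape (64–80 × 64–80 × 64–88 voxels) and spacing (1.4–2.0 mm per
axis). The bone is an analytic implicit field; the ground-truth mesh is
marching cubes of a 2× supersampled sampling of that field, and the CT
intensities are rasterized from that mesh by centre containment — so the
mesh and the voxel data are consistent by construction, and greedy masks are
supersets of the intensity-model bone voxels. Intensities: tissue
N(40, 15) HU, bone N(700, 100) HU, acquisition noise N(0, 20) HU — about
6 pooled standard deviations of contrast, which guarantees the task is
learnable by a tiny network.

What the phantoms do **not** model: real anatomical shape variation,
trabecular/cortical internal structure, partial-volume effects at the bone
boundary, beam hardening, metal artefacts (except as an explicit `implant`
corruption mode), reconstruction kernels. Passing the desk-scale study
therefore demonstrates that the pipeline's machinery — resampling, two-stage
cascade, transfer initialization, post-processing, mesh metrics — is
correct and trainable end to end; it does not certify clinical accuracy on
real CTs. Corruption modes (`implant`, `tilt`, `crop`) reproduce the defect
classes that motivated manual exclusion in clinical practice and are used
only in robustness tests, never in default cohorts.

## Desk-scale study

`experiment.run_study` is the package's end-to-end experiment at desk scale:
45 phantoms split 30 train / 5 validation / 10 test (the clinical 360/40
proportions at reduced scale plus a held-out test set), `base_filters=4`,
stage grids `48^3` and `64x48x48`. Stage 2 trains up to 45 epochs from
Glorot init; stage 1 starts from the transferred stage-2 weights and trains
up to 25 epochs — epoch caps chosen so the whole study (generation,
training, inference, evaluation) runs in well under half an hour on one CPU
core; within those caps the plateau schedule operates as configured.
Held-out evaluation reports mask-level Dice for each stage (mapped back to
the native grid), and mesh DSC / ASD / HD95 for the whole phantom and for
the left/right crest ROIs (8,000 samples per surface, 1 mm Dice pitch —
enough for ~1% metric noise at phantom scale).

Stage-level Dice is scored against the *greedy* mask — the target the
stages are trained to produce. Scoring against the centre-containment bone
voxels instead would cap thin-shell Dice near 0.83 regardless of network
quality, because the greedy target is deliberately dilated by about 0.7
voxel at the boundary. The mesh metrics are unaffected by this choice: they
compare the post-processed surface, where the one-voxel erosion has removed
the dilation, against the ground-truth mesh (measured ceiling of the
post-processing chain on a perfect stage-2 target: mesh DSC ≈ 0.93,
ASD ≈ 0.5 mm at phantom resolution).

## Numerical notes and edge cases

* Resampling maps output voxel centres into the input's index space with
  the outer physical extents aligned, so extents are preserved to within
  half an output voxel; interpolation is trilinear (intensities) or
  trilinear + 0.5 threshold (masks), nearest-neighbour on request.
* Marching cubes of a field whose range does not straddle the iso value
  returns an empty mesh, flagged by `len(mesh.faces) == 0`, not an error;
  the same convention propagates through clipping and ROI application.
* An all-background prediction raises `BoneNotFoundError` rather than
  producing an empty result silently.
* Ray-casting parity uses a fixed sub-voxel jitter of the triangle
  coordinates so vertical rays never hit vertices or edges exactly.
* Percentiles use linear (type-7) interpolation throughout.
* Voxelization ties (a surface passing exactly through a voxel centre) are
  resolved toward foreground.

## Known limitations

* The NumPy/numba network is single-core and desk-scale; the clinical-scale
  stage grids run inference fine, but training at clinical resolution calls
  for a GPU framework.
* Mesh Dice depends on the voxelization pitch; values at different pitches
  are not directly comparable.
* The phantom generator's realism limits are listed above; in particular
  boundary intensities switch sharply between tissue and bone statistics,
  with no partial-volume ramp.
* DICOM reading supports plain axis-aligned series only (no gantry tilt,
  no multi-frame files).
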