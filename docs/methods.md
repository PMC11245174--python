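# Methods

## Problem and pipeline

Quantitative assessment of carotid atherosclerosis from 3D black-blood MRI
(BB-MRI) rests on measuring the vessel wall in 2D cross-sections placed
perpendicular to the vessel centerline; oblique sections overestimate the
wall thickness. The pipeline implemented here covers:

1. centerline handling and a standardized 8-plane placement scheme
   (2 planes in the common carotid artery, 5 in the internal, 1 in the
   external, anchored at the flow-diverter landmark at the bifurcation);
2. perpendicular multiplanar reconstruction (MPR) of 25 mm / 0.195 mm
   patches, normalized to zero mean and unit variance;
3. a residual U-Net that segments each patch into background, vessel wall
   and lumen;
4. contour-based evaluation (Dice, Hausdorff distance, average contour
   distance) and clinical quantification (per-angle vessel wall thickness,
   12-segment bull's-eye, maximal VWT, ICC(3,1) and Bland-Altman agreement);
5. a leave-one-plane-out protocol testing whether a model trained on
   sparsely sampled plane positions generalizes to an unseen position.

Because clinical BB-MRI datasets of this kind are generally private, a
synthetic phantom generator stands in for them; every stage of the pipeline
is exercised end to end on phantoms with exact analytic ground truth.

## Phantom model

A phantom is a bifurcating tube: three straight branch segments (CCA
splitting into ICA and ECA) whose union of distance fields defines the
vessel, guaranteeing watertight geometry at the bifurcation. Lumen radius
and wall thickness are functions of the signed arc length from the flow
diverter and, for the thickness, optionally of the angular position, which
expresses eccentric walls and Gaussian stenosis bumps. Intensities follow
the BB-MRI ordering (lumen 0.1 < background 0.3 < wall 0.7 on a 0-1 scale);
rendering supersamples each 0.6 mm voxel (3x3x3 by default, 2x2x2 in the
protocol preset to bound runtime) and averages the tissue levels, giving
soft partial-volume edges rather than binary ones. Noise is additive
Gaussian — a simplification of the Rician noise of magnitude MRI that is
adequate at the simulated contrast levels. Two confound types can be
injected as Gaussian intensity blobs masked to their host tissue: bright
flow artifacts inside the lumen and dark calcifications inside the wall.

What the phantom does **not** emulate: pulse-sequence physics, coil/bias
fields, plaque texture, motion, curved branches, and realistic artifact
shapes (no quantitative description of flow-artifact geometry was
available, so artifact parameters are free knobs). Passing tests on
phantoms therefore demonstrate the correctness of the pipeline's geometry,
learning machinery and statistics — not clinical segmentation accuracy on
patient MRI.

## Cohort generator

Per-subject anatomy is drawn once per subject: CCA lumen radius
U(2.4, 3.2) mm tapering into the daughter branches with caliber ratios
ICA U(0.70, 0.90) and ECA U(0.55, 0.85) of the CCA; wall thickness
U(0.8, 1.3) mm; noise sigma U(0.02, 0.04); bifurcation azimuth uniform on
the circle; 40% of subjects receive a focal stenosis bump (peak
U(0.5, 1.5) mm, half of them eccentric), 30% a flow artifact and 25% a
calcification. These ranges are plausible for an elderly hypertensive
cohort (common carotid diameter around 6 mm, wall around 1 mm). Daughter
branches originate from laterally offset points at the flow divider, so
the two lumens are separate immediately distal to the bifurcation, as in
a real carotid Y-junction. The overlapping caliber ranges and the random
azimuth matter: they ensure that neither size nor side identifies the
target vessel in a patch -- only its centered position does -- so the
segmentation task actually requires the centerline anchoring that the
clinical protocol provides.

## Network and training

The residual U-Net: an encoder of
`depth` residual blocks (two 3x3 convolutions with batch normalization, a
1x1 strided convolution on the residual branch), the first `depth-1` blocks
halving the spatial size and the deepest keeping it, so a 128 px patch
reaches 4 px at depth 6; channel width doubles per level from
`base_filters` (16, ..., 512). The decoder mirrors the encoder with
stride-2 transposed convolutions and skip concatenation. Training uses
Adam at initial learning rate 0.001 with channel-wise sigmoid + binary
cross-entropy on one-hot targets, and augmentation with rotations in
[0, 180] degrees, integer translations up to 5 px per axis and scaling in
[0.9, 1.1].

Design points the architecture sketch leaves open, decided here:

* **Full-resolution skip.** The first encoder block downsamples
  immediately, so no encoder feature map exists at input resolution; the
  last decoder level therefore concatenates the network input itself.
  Without this path the decoder cannot express pixel-accurate boundaries
  (single-sample memorization empirically stalls at wall Dice ~0.97).
* **Initialization.** Convolutions use kaiming-uniform fan-in init; each
  block's last batch-norm gain starts at zero (blocks start as their
  shortcut); the output head starts with small weights and its bias at the
  logits of the training-set class frequencies. All are standard practices
  that shorten the early optimization transient, which matters for CPU-scale
  budgets; they change no stated hyperparameter.
* **"Binary cross-entropy" with three classes** is read as channel-wise
  sigmoid + BCE with argmax at inference; softmax cross-entropy is available
  via ``TrainConfig(loss="softmax_ce")``.
* Batch size 16 and ReLU activations are conventional defaults,
  configurable.
* No learning-rate schedule: only the initial rate is stated.
* The implementation is a small NumPy layer library with hand-written
  backpropagation (im2col convolutions over BLAS matmuls); gradients are
  verified against finite differences in the test suite. float32 is the
  compute dtype; float64 is available for gradient checking.

## Geometry conventions

World coordinates are millimetres. A plane frame is the right-handed triad
{axis_u, axis_v, normal} with the normal equal to the local centerline
tangent and axis_u the in-plane projection of the anterior axis (+y), so
patches are anatomically anchored and bull's-eye sectors can be labelled
anterior/posterior/right/left. Pixel (i, j) of an n x n patch sits at
``center + (i-(n-1)/2) * pixel * axis_u + (j-(n-1)/2) * pixel * axis_v``.
The grid is 128 px at 0.195 mm (25 mm / 0.195 mm = 128.2; the power-of-two
side is required by the five stride-2 halvings). Intensities are resampled
trilinearly (exact on linear fields), labels with nearest neighbour.

Default plane offsets from the flow diverter — CCA at 10 and 5 mm proximal,
ICA at 2.5/5/7.5/10/15 mm distal, ECA at 5 mm distal — are configurable:
the exact distances differ between clinical annotation protocols, so no
single set is canonical.

## Metrics and quantification

Contour distances are computed in mm after densifying polylines to at most
0.05 mm vertex spacing; each dense sample is measured against the other
polyline's segments exactly. This bounds the Hausdorff discretization
error well below the 3-decimal reporting precision. The wall, an annulus,
pools its inner and outer boundary into one contour set (switchable).
Dice is areal on masks; two empty regions score 1.0 by convention, and a
region missing from a prediction records Dice 0 with the patch diagonal as
a distance sentinel so aggregates stay defined.

Wall thickness uses radial ray casting from the centerline point: per ray,
the distance to the first inner-contour crossing (inner radius) and from
there to the first outer crossing (VWT). Rays with multiple inner
crossings (non-star-shaped lumen) use the nearest crossing and are
flagged; a nearest-point thickness operator is available as an
alternative. 360 rays per profile; 12 sectors of 30 degrees, sector value =
mean over valid rays; the maximal VWT is taken over rays, not sector means.
The angular origin is anterior, increasing clockwise viewed from proximal
to distal.

ICC(3,1) is the two-way mixed-effects, single-rater, consistency form
``(MS_rows - MS_err) / (MS_rows + (k-1) MS_err)`` with k = 2; it is checked
against a brute-force ANOVA table and against an independent statistics
package in the tests. Bland-Altman limits are mean +/- 1.96 times the
sample standard deviation (n-1) of the paired differences.

The plausibility rule rejects a segmentation if any lumen pixel is
4-adjacent to background (or touches the patch border, where the wall
cannot be verified), or if wall plus lumen has more than one 8-connected
component. Strict 4-adjacency for enclosure and permissive 8-connectivity
for cohesion are deliberate; rejected predictions stay in the metric
tables, flagged, mirroring how outliers are reported rather than excluded.

## Protocol scale

The default protocol preset trains the reference model M_R and three
leave-one-plane-out models (planes 1, 3, 8 — proximal CCA, the plane at
the bifurcation, and the ECA plane) on 40 synthetic subjects (one carotid
each, ~12% of subjects held out patient-wise), with a reduced network
(depth 4, 8 base filters) on 64 px / 0.39 mm patches for 30 epochs. These
sizes were chosen once so the full run completes in minutes on one CPU
core; the full-scale configuration (depth 6, 16 filters, 128 px
patches, 200 epochs, all eight planes) is expressible through the same
config. Per-model seeds derive from the root seed plus the held-out plane
id, so runs are independent but reproducible.

## Numerical choices and degenerate inputs

* Rasterization: pixel centers on a contour count as inside (deterministic
  ties-to-the-enclosed-region rule).
* Sub-pixel contours: 0.5-level marching squares on the binary region
  image, largest closed component, after 1 px zero padding so border
  regions still close; worst-case vertex error is about half a pixel.
* Rays through a polygon vertex are deduplicated by collapsing crossing
  parameters closer than 1e-9.
* Constant patches normalize to all zeros with a warning instead of
  dividing by a vanishing standard deviation.
* A flat thickness profile places the stenosis plane at the most proximal
  maximizer and logs the tie.
* NaN training loss aborts with diagnostics rather than continuing.

## Known limitations

The phantom's straight-branch geometry makes plane placement and truth
contours exact but omits curvature effects on the MPR; the noise model is
Gaussian; artifact geometry is invented. Clinical-grade accuracy numbers
cannot be established from synthetic data and none are claimed; the
protocol here tests the qualitative sparse-annotation property — that
leave-one-plane-out models match the reference model on their held-out
plane — at desk scale.
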