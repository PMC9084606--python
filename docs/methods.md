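# Methods

## Plane model and coordinate conventions

A standard MPR plane is parameterized by its center `A` (mm) and two
orthonormal in-plane direction vectors `e_u` (rows) and `e_v` (columns); the
normal `e_w = e_u × e_v` is always derived, never stored, so frames cannot
drift out of orthonormality. The volume coordinate system is right-handed,
in millimeters, origin at the geometric center of the volume, axes parallel
to the voxel axes, 0-based indices. Center-origin makes the translation
normalization symmetric: a normalized center component is
`A_i / (extent_i / 2)`, so anything inside the field of view lies in
[-1, 1]. Normalization does not clamp — augmented planes may legitimately
leave the field of view and the loss should see that (a warning is emitted).

Each body region carries an ordered triplet [axial, (semi)coronal, sagittal].
For the calcaneus the second plane is the oblique semicoronal plane;
elsewhere the three planes are mutually orthogonal.

## Rotation representations

Four bidirectional codecs map a rotation matrix to a bounded target vector:

* `euler_sincos` (6 values): intrinsic Z-Y-X Euler angles regressed as
  (sin, cos) pairs; decoding uses atan2 per pair, which is continuous in the
  regressed values and scale invariant. A degenerate (0, 0) pair decodes to
  angle 0 (documented tie-break). The Euler convention is a free choice:
  any fixed convention satisfies the round-trip contract, and the choice is
  isolated behind the codec interface.
* `quaternion` (4 values): unit quaternion (w, x, y, z); encoding applies the
  canonical nonnegative-scalar sign (tie broken by the first nonzero
  component positive) so the MSE loss never sees the double-cover ambiguity;
  decoding normalizes first and rejects near-zero vectors (< 1e-8).
* `six_d_xy` / `six_d_xz` (6 values): two matrix columns. Decoding normalizes
  the first vector, orthogonalizes the second against it (Gram–Schmidt) and
  restores the missing column by cross product so det(R) = +1. For `xz` the
  second regressed vector is the plane normal: the decoded columns are
  [a, b×a, b]. Decoding rejects near-zero or near-parallel inputs
  (threshold 1e-8 on the norm, 1 - 1e-8 on |cos|).

All encodings of exact rotations lie in [-1, 1] componentwise, and decoding
arbitrary (noisy) vectors always yields proper rotations — network outputs
can never produce an invalid plane frame.

## Augmentation and intensity normalization

Spatial training augmentation composes subsampling/cropping (T_r), isotropic
scaling (T_s, factor in [0.95, 1.05]), translation (T_t, ±12 mm/axis) and
rotation (T_R, three intrinsic Z-Y-X angles each uniform in ±45°) into one
homogeneous matrix `T_m = T_r·T_s·T_t·T_R` applied exactly as written; the
volume is pulled through the map with a single trilinear interpolation pass
(out-of-field voxels filled with air, -1000 HU — the kernel and fill value
are declared choices, not prescribed ones). Each spatial op is independently
active with probability 0.5. x-mirroring (probability 0.5) is a separate
diagonal factor; labels are pulled back through the inverse of the full map,
directions renormalized, and the normal re-derived as `e_u × e_v`, which
flips the frame handedness together with the anatomy — this is what makes
mirroring a left/right-handedness simulation rather than a plain reflection
of the annotation. Cropping maps the output grid to the central physical
region and is exposed as `crop_fraction` (default 1.0 = full field of view).

Intensity normalization: `c(x) = clip((f·(x + 1000) - 510) / 1530, 0, 1)`
(the clip bounds are the [-490, 1040] HU window after the +1000 shift;
f is the random calibration factor in [0.95, 1.05]), followed by the
logistic window `w(x) = 1 / (1 + exp(g·(0.5 - x)))`. Taking the gain
formula's min/max on the HU scale would give y = 30.6 and an undefined
log((1-y)/y); the only consistent reading is that they refer to the rescaled
unit range, so y = 0.02 and `g = ln(49)/0.4 ≈ 9.7296`. The window maps air
to ≈ 0.0076 and metal to ≈ 0.9924, compressing the variance of the two
uninformative tails; it is strictly monotone and symmetric
(w(x) + w(1-x) = 1).

## Networks and training

The trunk stacks five blocks of (3³ same-padding conv → ReLU → batchnorm →
2³ max-pool with ceil mode), channels 1→8→16→32→64→128 on a 72³ input; the
last block replaces its pool with an adaptive max-pool to 4×5×4 so the
flattened feature vector has 10,240 entries, feeding the fully connected
head 10240→1300→50→n. The adaptive 4×5×4 pooling and the 128-channel final
block are this implementation's choices: isotropic 3³ kernels on a 72³ input
cannot produce anisotropic intermediate grids, and 4·5·4·128 is the unique
isotropic-friendly factorization of the 10,240-dimensional flatten.

Three modes: `baseline` (one network per region), `single_head` (one network
for all regions), `multi_head` (shared trunk, one head per region). In
multihead training, batches are processed per region subgroup so each
sample's gradient reaches only its region's head — exactly the masked
backward pass — while the trunk accumulates all gradients; loss contributions
are weighted by subgroup size so the total equals the plain MSE over every
output node of the batch. The MSE is averaged (not summed) over nodes; the
two differ only by a learning-rate scale.

Layers are float32 numpy with manual backprop (convolution as one matmul per
kernel offset). Weights use He-normal initialization; the output layer's
weights are additionally scaled by 0.01 so a freshly initialized head starts
near zero instead of emitting O(3) predictions for targets bounded in
[-1, 1] — without this the first SGD steps are dominated by enormous error
gradients and the trunk collapses to predicting the dataset mean. Batch-norm
uses batch statistics in training and frozen running statistics (momentum
0.1, eps 1e-5) at evaluation. The optimizer is minibatch gradient descent
with classical momentum; the full-scale defaults are lr 0.00164 decayed by
0.27291 every 75 epochs, momentum 0.957437, batch size 9, 400 epochs.
Checkpointing keeps the final epoch (no validation-based model selection).
Augmentation applies during training only. A NaN loss aborts with a
diagnostic. Given a seed, data order, initialization and therefore the whole
run are deterministic.

Oversampling for imbalanced multi-region datasets draws samples with weight
proportional to 1/(count of the sample's region), equalizing expected
per-region frequencies.

## Postprocessing

The three planes are regressed independently (no orthogonality penalty in
the loss), so consistency is restored algorithmically, with the axial plane
as the reference:

1. In-plane correction: for the (semi)coronal and sagittal planes, the
   intersection direction `v = e_w_axial × e_w_plane` is computed and the
   in-plane frame rotated about the plane normal so `e_u` is parallel to v.
   Aligning the *row* direction with the axial trace matches radiological
   display convention (the axial trace runs horizontally on coronal and
   sagittal views). Antiparallel configurations are rotated all the way into
   alignment rather than by the smaller angle, so 180° in-plane errors are
   corrected. Parallel normals skip the plane with a warning.
2. Sagittal orthogonalization (orthogonal-plane regions only, i.e. not the
   calcaneus): the sagittal normal is replaced by
   `±(e_w_axial × e_w_coronal)`, sign nearest the regressed normal; the
   in-plane frame is rebuilt by projecting the previous `e_u` onto the new
   plane. Only the sagittal normal is ever re-orthogonalized.

Centers and the axial plane are never modified, and the combined operator is
idempotent. The canonical phantom frames were chosen so a geometrically
consistent triplet is an exact fixed point.

## Evaluation metric

Per plane, against the reference annotation: `d = |(A_pred - A_ref)·e_w_ref|`
(mm; in-plane center offsets are invisible by construction), `ε_n` = angle
between normals (degrees; flips score ≈180°, deliberately — plane flips are a
real failure mode and no flip-forgiveness is applied anywhere), `ε_i` = mean
unsigned angle of the predicted `e_u`/`e_v` after projection onto the
reference plane. The per-volume score is
`p = mean_planes(0.2·d + 0.6·ε_n + 0.2·ε_i)`, mixing mm and degrees by
design: the normal is weighted highest because out-of-plane error is the
hardest to fix manually. Angles use the atan2(‖cross‖, dot) form, which is
exact at 0° and 180° where arccos loses precision. Cross-validation
aggregation takes the median of each metric within a fold, then mean and
sample standard deviation across folds (a single fold reports sd 0 with a
flag).

## Synthetic phantoms

Each phantom composites analytic shapes in a canonical frame: a cortical
shaft (cylinder along -z, 12 mm radius, HU 1200), a joint head (ellipsoid
24×18×15 mm at the origin, HU 900), a soft-tissue envelope (HU 50), a 10 mm
marker sphere at +x (HU 1500) and an 8 mm marker at +y (HU 1300), plus an
optional 6 mm metal sphere (HU 3000). The two markers and the one-sided
shaft break every rotational and mirror symmetry, so the pose — including
left/right handedness — is unambiguous and learnable. Shapes are rendered by
signed-distance thresholding with a one-voxel linear edge ramp (the
ellipsoid distance is a first-order approximation, exact at the surface),
Gaussian HU noise (default σ 20 HU) is added after compositing, and the
ground-truth triplet is the canonical triplet mapped by the sampled rigid
pose — exact by construction. Default grid 128³ at 1.25 mm (160 mm cube,
matching the clinical field of view); a 512³ mode exists for fidelity.

What the phantoms do **not** emulate: real bone morphology and texture,
joint articulation and pose-dependent deformation, reconstruction artifacts
(beam hardening, scatter, metal streaks), truncated anatomy at the field of
view border, and inter-patient anatomical variability. Passing the recovery
experiment therefore demonstrates that the pipeline — geometry, codecs,
augmentation, training, decoding, postprocessing, metric — is correct and
that the network can regress rigid pose from volumetric images; it does not
demonstrate clinical-grade accuracy on real CBCT volumes.

## Scaled-down recovery experiment

The end-to-end experiment trains a reduced architecture (32³ input, channels
4→8→16→32, head 256→64→27, 6Dxy codec, ~37k parameters) on 200 phantoms
rendered directly at 32³ (5 mm voxels, 160 mm field of view) with poses
within ±30° and ±10 mm, for 30 epochs (SGD, lr 0.02 halved every 10 epochs,
momentum 0.9, batch 10, no online augmentation — the pose variation is in
the data, and augmentation correctness is covered by its own consistency
tests). Evaluation on 50 held-out phantoms reports median d, ε_n, ε_i and
the weighted score with and without postprocessing. These problem sizes
were chosen so a full run finishes in a few minutes on one CPU; the reduced
training hyperparameters were selected from training-loss convergence on
the synthetic task. With seed 1 the run reaches median d ≈ 2.6 mm and
median ε_n ≈ 7.2°, and postprocessing improves the median score (≈5.8 vs
≈6.1 raw).

## Known limitations

* No GPU path; the numpy implementation is sized for the reduced experiment,
  and full-scale 72³ training at 400 epochs, while functional, is slow.
* Volumes must be axis-aligned (no oblique direction cosines) — DICOM
  patient-orientation handling is out of scope.
* Exactly three planes per region; the fold splitter groups by synthetic
  patient id but implements no origin stratification beyond that.
* The ellipsoid signed distance is approximate away from the surface, which
  only affects the sub-voxel edge ramp of the rendering.
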