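# Methods

`petctseg` implements a fully automatic route from co-registered PET/CT
volumes to a trained CT bladder-segmentation network, with no manual
delineation anywhere: PET supplies the labels, CT supplies the images.
This note records the models, the parameters that matter, the synthetic data
the package is validated on, and the design choices made where the design was
genuinely open.

## Weak labels from PET thresholding

¹⁸F-FDG accumulates in the urinary bladder, so in an FDG-PET volume the
bladder is the dominant bright structure.  The labeller computes one
threshold per patient dataset,

    T = SUVmax · f,     f = 0.2 by default,

where SUVmax is the maximum over the whole 3D PET volume (per dataset, never
per slice), and labels a voxel foreground iff its value is **strictly
greater** than T.  "Above the threshold" is read literally: a voxel exactly
equal to T is background.  The equal-value case has measure zero on real
data; it is pinned by a unit test so the convention cannot drift.

PET is always resampled onto the CT grid (trilinear, pixel-center
convention) before thresholding, never CT onto PET: the masks must align
pixel-for-pixel with the CT slices used for training.  Computing T *after*
resampling is safe because trilinear interpolation is max-bounded — it can
never manufacture a value above the original maximum.  No connected-component
filtering is applied; any uptake above T becomes foreground.

From the binarized volume, every CT slice whose mask contains at least one
foreground pixel is extracted as a training pair; a `margin` parameter
optionally includes empty-mask context slices on each side of a foreground
run (default 0, since whether "slices around the bladder" includes empty
context slices is a modelling choice, both readings are exposed).

## Augmentation with exact accounting

The augmentation scheme is a full cross-product of explicit parameter lists:

* rotation angles (degrees, |θ| ≤ 180, always including 0),
* x and y scale factors (each within 1 ± 0.15, always including 1.0),
* noise specifications (type ∈ {gaussian, uniform, salt_pepper} with
  sd ≤ 10 / amplitude ≤ 10 / density ≤ 0.5, plus a copy count).

Geometric transforms are applied identically to image and mask about the
image center with the canvas size unchanged; the image is interpolated
bilinearly with out-of-field pixels filled with the image minimum, the mask
by nearest neighbour (so labels stay exactly binary) with 0 fill.  Noise is
added to images only, never to masks.  The output count is exact:

    variants/slice = |angles| · |sx| · |sy| · (1 + Σ copies).

The default configuration — angles {−45°, 0°, +45°}, scales {0.9, 1.0, 1.1}
in both axes, one zero-mean Gaussian (σ = 5) copy of every transformed slice
— realizes magnification ×27 by transformation and ×54 in total, so a
630-slice training set becomes exactly 34,020 pairs.  Explicit lists are the
configuration surface (rather than "number of rotations"-style counts)
precisely so this accounting is verifiable.

The train/test split is at patient level: whole patients are shuffled with a
seeded RNG and assigned greedily to the training side until the training
slice count first reaches the requested fraction (default 0.8).  No patient
ever contributes slices to both sides, and the test side is never augmented.

## Synthetic phantom

The phantom generator replaces clinical PET/CT with a controlled pair of
volumes whose ground truth is known exactly, emulating the features the
pipeline must cope with:

* **CT**: soft-tissue background (40 HU) with the bladder only
  `soft_tissue_contrast` = 12 HU above it; a high-attenuation elliptical
  "pelvic ring" (≈800 HU) around the field; optional radial sinusoidal
  streaks inside the ring (a qualitative stand-in for beam-hardening
  artifacts between dense bone — not a CT physics simulation); additive
  Gaussian noise (σ = 5 HU default).
* **PET**: background 0.5 with an ellipsoidal bladder at
  `uptake_ratio` × background (default 15), blurred in-plane with a 0.7 mm
  Gaussian (partial-volume stand-in) and rendered at in-plane resolution
  coarser than CT by `pet_downsample_factor` (default 2, via block
  averaging, with the PET grid origin at the block centers).
* **Truth**: the ellipsoid rasterized on the CT grid (pixel-center inclusion;
  the voxel nearest the center is always included so the degenerate
  small-axis limit is a single-voxel bladder, not an empty mask).

Default geometry: 12 slices of 128×128 at (4, 1, 1) mm spacing, bladder
half-axes (18, 40, 35) mm.  The bladder is deliberately large relative to
the total PET smoothing kernel: fixed-fraction thresholding systematically
dilates the mask by roughly the smoothing scale (the 20% level sits below
the half-maximum of a blurred edge), and the geometry is chosen so this bias
costs a few percent of Dice at most — the regime in which the threshold rule
is a valid weak labeller, which is exactly the assumption the pipeline rests
on.  Cohort generation jitters bladder size, position, contrast and uptake
per patient from a seeded RNG, and can fix the per-patient number of
bladder-bearing slices exactly (any cohort total, e.g. 845 slices over 29
patients, is reachable with unequal counts).

What the phantom does **not** emulate: attenuation/scatter physics,
non-bladder FDG uptake (kidneys, ureters, tumours), irregular bladder
shapes, the bladder–prostate interface, and real CT texture.  Tests passing
on phantoms therefore validate the pipeline's mechanics and its core
thresholding assumption, not clinical segmentation accuracy.

## Network architectures

Both families map a 1-channel CT slice to 2-class logits at input
resolution; all convolutions are stride-1 same-padded (downsampling is 2×2
max pooling), so every layer runs on one fast im2col path of the numpy
autodiff core in `petctseg.nn`.

**FCN-8s.** A VGG-16-shaped backbone (13 3×3 convolutions in five stages,
widths 64…512 scaled by `width_scale`), fully connected layers realized as a
7×7 and a 1×1 convolution, and a 1×1 score head at stride 32.  The score map
is upsampled ×2 and summed with a 1×1 score of the fourth pooling stage,
upsampled ×2 and summed with a score of the third pooling stage, then
upsampled ×8.  Skip score convolutions are zero-initialized so optimization
starts from the coarse stride-32 prediction.  Input sides must be divisible
by 32.

**Upsampled ResNet.** A residual backbone of four stages (widths 64…512
scaled), stage strides 2, 2, 2, 1; the last stage keeps resolution and uses
atrous (dilated) convolution with rate 2 instead, so the deepest feature map
is input/8.  A 1×1 score head and one fixed bilinear ×8 interpolation
produce full-resolution logits.  Inputs must be divisible by 8.  The stage
schedule fixes output stride 8; it is a width-/depth-scaled stand-in, not a
claim of layer-level identity with any particular deep ResNet variant.

All upsampling uses transposed convolution with a **fixed** separable
bilinear kernel of side 2f − (f mod 2) (peak 1 at the center, a partition of
unity on the interior); these kernels are excluded from the trainable
parameters.  Backbones are trained from scratch on phantom data at reduced
width — ImageNet-pretrained checkpoints are intentionally not a dependency,
so the transfer-learning benefit of full-scale training is out of scope.

## Training protocol

Adam with a fixed learning rate of 1e-4, batch size 1 (one image per step,
hence no batch normalization anywhere), pixelwise softmax cross-entropy.
Images are visited in cyclic order and initialization is seeded, so a run is
reproducible to the bit.  Prediction is per-pixel argmax with ties resolved
to background (the conservative choice; an all-zero network predicts empty
masks).

Inputs are standardized per image with robust statistics — median and
1.4826·MAD, clipped to ±20 — rather than mean/std.  CT intensity
distributions are heavy-tailed: dense bone spans hundreds of HU while the
bladder/soft-tissue contrast is ~10 HU, and a mean/std scale puts that
contrast at amplitude ~0.05 where fixed-step training cannot exploit it.
The robust scale keeps the soft-tissue signal at order 1.

Desk-scale problem sizes used by the test suite and the acceptance script:
10 slices of 64×64 (2 mm in-plane), `width_scale` 0.125, 600 iterations.
At these sizes both families memorize the training slices to Dice ≥ 0.9 —
the memorization-capacity check that stands in for full-scale training,
whose published quantitative results additionally depend on external
clinical data and pretrained backbones and are not reproduced here.

## Evaluation metrics

Per slice: confusion counts, TPR = TP/(TP+FN), TNR = TN/(TN+FP),
DSC = 2|Sg∩Sp|/(|Sg|+|Sp|), and the symmetric Hausdorff distance
HD(A,B) = max(h(A,B), h(B,A)) with h the directed max–min Euclidean
distance.  HD is computed on foreground pixel coordinate sets (interior
points never realize the max–min, so this equals the contour-based value)
and reported in pixel units.  Metrics with an empty denominator (DSC of two
empty masks, HD against an empty set, TPR without foreground) are flagged
undefined; cohort means are arithmetic over defined values, with the number
of excluded pairs logged and reported — zero-filling undefined slices would
silently bias means, exclusion keeps the estimate interpretable.

## Numerical and interface choices

* One grid convention everywhere: axes (slice, row, col), 0-based indices,
  pixel-center physical coordinates; this avoids half-pixel drift between
  masks and images.
* DICOM series are read-only input (pydicom, slices sorted ascending along
  the patient axis, mixed-modality series rejected); NIfTI is the volume
  interchange format; slice datasets are 16-bit PNG images and 8-bit {0,255}
  PNG masks with a TSV manifest carrying per-slice provenance (source slice,
  angle, scales, noise).  The export is lossless for integer-valued images
  (CT is integer HU in practice); fractional intensities are rounded once at
  export.
* The pipeline driver derives every stage seed from one master seed
  (`numpy` SeedSequence), logs per-stage slice counts, and writes a JSON run
  report; re-running with the same seed reproduces all artifacts
  bit-for-bit.

## Known limitations

* The phantom's streak/noise model is qualitative; no claim of CT physics.
* Thresholding dilates masks by the PET smoothing scale; on small bladders
  (a few PET voxels across) the weak labels degrade, matching the known
  behaviour of fixed-fraction thresholding on small objects.
* Networks are trained from scratch at reduced width; absolute segmentation
  accuracy on clinical data is out of scope.
* No post-processing (e.g. CRF boundary refinement) is applied to
  predictions.
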