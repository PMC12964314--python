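# Methods

This note records the models, conventions and numerical choices behind
`planistem`, in the order the pipeline runs, together with the design
decisions that were genuinely open and the limitations of the synthetic
evaluation.

## Coordinate and plane conventions

Volumes are indexed `(z, y, x)` with `z` the axial axis and row 0
superior; pixel indices are 0-based and refer to pixel centers; angles
are degrees, counter-clockwise positive; all image interpolation is
linear unless stated otherwise. A candidate midsagittal plane is
parameterized by yaw θ (rotation of the plane normal within the axial
(y, x)-plane), roll φ (within the coronal (z, x)-plane) and a signed
perpendicular distance s from the volume center in voxels. The unit
normal is `n = R_roll(φ) R_yaw(θ) e_x`, i.e.
`n = (sin φ cos θ, sin θ, cos φ cos θ)` in (z, y, x) components, and the
plane is `{p : n · (p − c) = s}`.

Two projection identities matter for detection. In an axial slice at
height z₀ the fissure line has normal direction
`tan θ_ax = tan θ / cos φ` and center-referenced offset
`s_ax = (s − sin φ cos θ (z₀ − c_z)) / N` with
`N = hypot(sin θ, cos φ cos θ)`. The detector inverts both exactly: θ is
recovered from θ_ax once φ is known, and each per-slice offset is
corrected for its height before the median. Because the offsets are
linear in z₀, extrapolating them to the central height also yields an
unbiased midline column for the roll-symmetry stage — using the raw
median there biases the roll estimate when |φ| is large.

## MSP detection

* Axial slices are analyzed at fractions {0.15, 0.20, 0.25, 0.30, 0.35}
  of the foreground extent measured from the superior end (the "upper
  brain", above the brainstem). The binarization threshold for the
  center of mass is Otsu's; both are configurable (`MspConfig`).
* The Radon transform averages intensities along lines sampled at unit
  steps with bilinear interpolation; the search grid is
  θ ∈ [−10°, 10°] step 0.25°, s ∈ [−20, 20] px step 0.5 px. Cells whose
  line intersects the support in fewer than 16 samples are invalid and
  never considered minima. Tie-break at the minimum: smallest |θ|, then
  smallest |s|, then the smaller signed values.
* Roll scoring rotates the central coronal slice of the yaw-aligned
  volume about its center and scores the negative mean absolute
  difference to its mirror about the midline column over foreground
  pixels (> 10% of the slice maximum). Rotating about the image center
  rather than a point on the midline costs O(s·φ²) px — under 0.05 px
  in the accepted range.
* The plane image is standardized to 176 × 256 pixels with a
  pixel-center-preserving rescale from the native sagittal geometry;
  the 128 × 128 ROI sits at offset (40, 64) — horizontally centered,
  shifted toward the inferior half where the brainstem lies. MSP pixel
  spacing is `voxel_size × native_extent / standard_extent` per axis,
  so isotropic voxels give isotropic MSP pixels only when the native
  sagittal grid is proportional to 176 × 256.

Recovery accuracy on noiseless phantoms is ≤ (1°, 1°, 1 px) over the
full accepted range, and unchanged under Rician noise at SNR 25, where
line averaging suppresses the per-pixel noise.

## Segmentation network and loss

The U-Net is the standard encoder–decoder: per level two 3×3
convolutions (ReLU) and a 2×2 max-pool; a two-convolution bottleneck;
per decoder level nearest ×2 upsampling, a 2×2 convolution halving the
channels, skip concatenation and two 3×3 convolutions; the head is one
3×3 convolution to 2 channels and a 1×1 convolution to 1 channel with a
logistic output. Depth 5 with widths 64–1024 gives exactly 31,031,685
trainable parameters. The two head convolutions are linear: in early
experiments a ReLU on the 2-channel bottleneck died irrecoverably in
about half the runs (both units inactive everywhere, collapsing the
output to a constant), and nothing downstream can recover from that.

The loss is the sum of a smoothed Dice loss
(ε = 1 in numerator and denominator, handling empty masks) and a
weighted binary cross-entropy summed over pixels with
`w[i] = log(1 + |I|/|I_k(i)| + 1_C(i)·|I|/|C_k(i)|)`; contours use
4-adjacency (configurable to 8), with C₁ the structure pixels touching
background and C₀ the background pixels touching structure; image
borders count as background. Probabilities are clipped to
[10⁻⁷, 1 − 10⁻⁷]. Both classes must be present — the weights divide by
the class sizes.

The network, backpropagation and Adam (lr 10⁻³, β 0.9/0.999) are
implemented directly in NumPy (`_nn.py`): convolutions as
shift-and-tensordot sums, max-pool routing by explicit argmax. Gradients
are verified against central finite differences to ~10⁻⁶ relative error
in float64; training runs in float32. Training is exactly reproducible
given the seed.

Training protocol: 30 epochs, batch 4, on-the-fly augmentation with
shifts ±10 px, rotations ±15°, zooms 0.8–1.2 applied identically to
image (linear) and mask (nearest); an augmented sample that loses its
foreground falls back to the original pair. Model selection keeps the
weights with the best validation combined loss; plain pixel accuracy is
available as an alternative metric but is near-degenerate under the
strong class imbalance (all-background already scores ≈ 0.97). One
independent model is trained per task. The CPU-scale configuration used
throughout the tests is depth 3, base width 8 (29,461 parameters), 64
training scenes — enough to reach held-out Dice ≈ 0.99 on the pons-area
task. The midbrain measurement ellipse, the smallest and
lowest-contrast region, converges slowest and gets 45 epochs where used
for end-to-end measurements.

## Planimetry

Areas are foreground pixel counts × pixel area; no polygonal boundary
area is involved. Boundary points are foreground pixels with at least
one 4-neighbor outside the foreground, as pixel-center coordinates.
The ellipse fit is the direct algebraic least-squares conic fit
constrained to ellipses (Halir–Flusser, via scikit-image); degenerate
inputs (< 5 points, collinear sets, non-elliptical solutions) raise
with a reason. The diameter is twice the semi-minor axis, converted to
mm; anisotropic pixels are refused (resample first).

On the mask→diameter path the fitted semi-axes are inflated by 0.5 px
(`fit_mask_ellipse`): boundary pixel centers lie on average half a
pixel inside the continuous outline that produced the mask, and the
uncorrected fit is biased small by ≈ 0.45 px per axis — several percent
for structures of this size. With the correction the
rasterize → boundary → fit round trip recovers minor-axis diameters
within 2% for semi-axes ≥ 8 px; below that, quantization noise grows
quickly, which is why the phantom's measurement ellipses are sized to
stay at or above that regime.

## Evaluation metrics

DICE = 2|A∩B|/(|A|+|B|); AD = (|A|−|B|) × pixel area, kept signed;
RAAD = 2||A|−|B||/(|A|+|B|) × 100; ADD = |diam A − diam B|;
RADD = 2|diam A − diam B|/(diam A + diam B) × 100 (reported in percent);
HAUS is the symmetric Hausdorff distance between the 4-neighbor
boundary point sets with Euclidean pixel-center distances, in pixels by
default with mm optional. Conventions: two empty masks give DICE 1
(flagged); one empty mask gives DICE 0 with HAUS undefined (flagged).
Set summaries report mean, SD (n−1) and the normal-approximation 95% CI
(mean ± 1.96 SD/√n), excluding and counting empty-prediction failures.
Agreement analysis reports the OLS R² of automated on reference values
and Bland–Altman mean difference with limits mean ± 1.96 SD.

The noise sweep corrupts each scene at each SNR (Gaussian or Rician),
predicts, and records mean Dice (failures contribute 0) and the
zero-output rate. SNR is defined as mean foreground intensity over
noise σ, with foreground = pixels above half the image maximum — the
source material never defines its SNR reference, so one simple
convention is fixed and documented here. With the phantom-trained model
the sweep reproduces the qualitative threshold behavior: essentially
unchanged accuracy down to SNR ≈ 15 and collapse at SNR 5.

## Synthetic phantom

The generator emulates exactly the features the pipeline relies on:

* a bright head ellipsoid (semi-axes ≈ 0.46/0.42/0.40 of the volume
  extents) with a smooth sigmoid edge, centered on the plane so the
  whole object is mirror-symmetric about it;
* a dark planar fissure: a Gaussian band of width `fissure_width`
  (default 3 voxels) reducing intensity by `fissure_contrast` (default
  0.6) — chosen so the fissure is clearly the darkest linear structure,
  as in T1 images;
* low-frequency mirror-symmetric texture (±4%);
* midline structures in MSP pixel units: the midbrain as two
  overlapping ellipse lobes minus a superior notch (a bean with
  peduncles), the pons as a larger filled ellipse; each structure body
  is brighter than background and each measurement-ellipse core
  brighter still, so all four tasks are learnable from intensity. Poses
  are jittered within bounds; one scale and one vertical shift are
  drawn for the whole brainstem so midbrain and pons stay disjoint
  (pixels inside both templates are rendered, and labeled, as pons);
  low-order radial deformations add outline variability. Ground-truth
  masks are exact pixel-center rasterizations, and the stored truth
  ellipses rasterize back to the ellipse-region masks identically.
* scene images carry a 0.7 px Gaussian PSF (masks stay crisp),
  emulating the partial-volume softness of a resampled MRI slice;
* noise: Gaussian, or Rician (`sqrt((I+n₁)² + n₂²)`), at a prescribed
  SNR; on zero signal the Rician model reduces to the Rayleigh law used
  to validate it.

What the phantom does **not** emulate: gyri/sulci, CSF spaces, skull
and scalp, bias fields, lesions, contrast agents, anisotropic
acquisition, or anatomically realistic boundary contrast between
brainstem substructures (the paper's hardest regions). Passing tests
therefore demonstrate the correctness of the geometry, losses,
measurements and the learning machinery — not clinical-grade
segmentation accuracy on real MRI.

## Problem sizes in the test suite

Detection tests use (88, 128, 128) volumes (half the native MSP grid →
isotropic 0.5 mm MSP pixels); one identity-geometry test uses
(176, 256, 129) so the central sagittal slice lies on the voxel grid;
end-to-end pipeline runs use (132, 192, 192) (isotropic 0.75 mm MSP
pixels), the scale at which the extraction's interpolation softness
matches the PSF the training scenes emulate. Networks are the depth-3,
base-8 configuration. These sizes are the package's scaled-down study
conditions; the full-size defaults (176 × 256 × 256, depth-5 U-Net)
run through exactly the same code paths.

## Known limitations

* The roll estimate is the least accurate plane parameter (errors up to
  ≈ 0.8° within the ±8° range) because the symmetry score is a shallow
  function of φ near the optimum.
* Diameters of very small regions (semi-minor < 8 px) are
  quantization-limited; a geometric-distance ellipse fit would reduce,
  not remove, this.
* The NumPy backend trains small networks on a CPU; the canonical
  31M-parameter configuration is described and countable but not
  practical to train there.
* `detect` assumes the fissure is the darkest line through the
  upper-brain slices; a volume without that property (e.g. heavy
  pathology crossing the midline) fails loudly rather than gracefully.
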