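# planistem

Fully automated MRI planimetry of brainstem structures.

Planimetric measurements — midsagittal areas and anteroposterior
diameters of the midbrain and pons — are established atrophy markers in
multiple sclerosis and other neurodegenerative disease, but they are
conventionally obtained by hand: an expert locates the midsagittal plane
(MSP), draws polygons around the structures, and fits ellipses for the
diameters. `planistem` automates the whole chain on a 3D T1-weighted
head volume:

1. **MSP detection.** An upper-brain axial slice is binarized (Otsu) and
   its center of mass taken as origin for a Radon transform — the mean
   intensity along lines indexed by normal direction θ and signed offset
   s. The dark interhemispheric fissure appears as the sinogram minimum
   (θ\*, s\*), giving the yaw angle and in-slice offset. The roll angle
   φ\* is found by rotating the central coronal slice of the yaw-aligned
   volume over candidate angles in (−10°, 10°) and maximizing mirror
   symmetry about the midline column. Per-slice line estimates from
   several axial heights are combined by the median. The plane
   {p : n(θ\*, φ\*)·(p − c) = s\*} is resampled to a standardized
   176 × 256 MSP image and a 128 × 128 brainstem ROI is cropped.
2. **Segmentation.** Four independent U-Nets (midbrain/pons ×
   area/diameter region) map the ROI to probability masks P = U_θ(F),
   thresholded at 0.5. The canonical architecture (depth 5, widths
   64–1024, 2-channel 3×3 + 1-channel 1×1 head, logistic output) has
   exactly **31,031,685** trainable parameters. Training minimizes

   L(G, Ĝ) = L_Dice(G, Ĝ) + L_WCE(G, Ĝ),

   where L_Dice = 1 − 2ΣᵢGᵢĜᵢ / (ΣᵢGᵢ + ΣᵢĜᵢ) and L_WCE is a binary
   cross-entropy with per-pixel weights
   w[i] = log(1 + |I|/|I_k(i)| + 1_C(i)·|I|/|C_k(i)|), so minority-class
   and contour pixels dominate the gradient. Training runs 30 epochs at
   batch size 4 with random shifts (±10 px), rotations (±15°) and zooms
   (80–120%), keeping the best-validation weights.
3. **Planimetry.** Areas are foreground-pixel counts times the pixel
   area. Diameters are the minor axis of a direct least-squares
   (algebraic) ellipse fit to the mask's boundary points.
4. **Evaluation.** DICE, AD, RAAD, ADD, RADD and the boundary Hausdorff
   distance; mean/SD/95% CI summaries; OLS R² and Bland–Altman limits of
   agreement; and a noise-robustness sweep (Gaussian and Rician noise at
   controlled SNR) that records mean Dice and the rate of empty
   segmentations.

Because clinical MRI cannot be shipped with the code, the package
includes a synthetic phantom generator with exact ground truth: an
ellipsoidal head with a dark planar fissure at known yaw/roll/offset,
mirror-symmetric texture, and bean/oval brainstem-like structures on the
midplane. Every stage is developed and tested against these phantoms.

## Worked example

```python
from planistem import (PhantomSpec, make_volume, detect, build_unet,
                       UNetConfig, measure)

print(build_unet(UNetConfig())["total_params"])
# 31031685

spec = PhantomSpec(shape=(132, 192, 192), fissure_yaw=4.0,
                   fissure_roll=-2.0, fissure_offset=3.0, seed=7)
pv = make_volume(spec)
plane, msp, roi = detect(pv.intensities)
print(f"yaw={plane.yaw:.2f} deg  roll={plane.roll:.2f} deg  "
      f"distance={plane.distance:.2f} px")
# yaw=4.00 deg  roll=-2.00 deg  distance=2.99 px

report = measure(pv.roi_truth.masks, roi.pixel_spacing)
print(report.midbrain_area, report.pons_diameter)
# 412.88 mm^2 and 23.19 mm (at 0.75 mm MSP pixels)
```

The detector recovers the planted plane (4°, −2°, 3 px) to within its
grid resolution; `measure` turns the four ground-truth masks into areas
(mm²) and ellipse-fit diameters (mm).

A command-line interface mirrors the library:

```
planistem simulate --out-dir data --n 3 --seed 1
planistem detect-msp --in data/phantom_000.nii.gz --out-dir out
planistem train --task pons_area --out weights/pons_area.npz
planistem run --in data/phantom_000.nii.gz --config config.yaml
planistem batch --config config.yaml --out results.csv data/*.nii.gz
```

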