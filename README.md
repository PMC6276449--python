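# sddliver

Fully automatic liver segmentation in abdominal CT slices, with 3D surface
reconstruction — a training-free, heuristic pipeline built on
slope-difference-distribution (SDD) multilevel thresholding.

## The problem

The liver in axial CT touches organs (stomach, kidney, heart) and abdominal-wall
tissue whose intensities can be indistinguishable from the liver's own, and its
2D cross-section changes shape dramatically from slice to slice.  Plain
thresholding therefore cannot isolate it.  This package segments the liver by
first segmenting everything *around* it — bones, the whole body, the adjacent
organ — and turning those results into geometric constraints, then stacks the
per-slice boundaries into a 3D surface.  It is aimed at researchers who need a
deterministic, training-free baseline for liver segmentation, or a testbed for
the individual algorithms (multilevel histogram thresholding, Ising-prior
denoising, constraint-based segmentation, contour-stack reconstruction).

## Method

Per slice, with intensities rescaled to {1,…,255}:

1. **Thresholds (SDD).** The histogram `P(x) = F_x / max_j F_j` is band-limited
   by a DFT low-pass filter of bandwidth `W`.  At every interior intensity `i`
   two OLS lines are fitted over the `N` samples left and right of `i`; the
   slope difference `s(i) = a_r(i) − a_l(i)` peaks where the histogram turns
   upward fastest.  Class-separating valleys are read off as the positive
   `s`-maxima paired between adjacent histogram modes, giving thresholds
   `T2 < T4 < T3 < T1` for body, liver, adjacent organ and bones.
2. **Constraints.**
   `I_bones = [I ≥ T1]`; its blobs split into flank ribs and the central spine,
   whose centroids fix a least-squares quadratic rib curve `col = f(row)`.
   `I_body = [I ≥ T2]` (denoised, opened, filled); eroding it by the mean rib
   width `N_c` and subtracting leaves the body-margin ring `I_cir`.
   The adjacent organ `I_stm = [I ≥ T3]` is Ising-ICM denoised, bone-subtracted,
   opened, restricted to the spine's organ side and closed into one blob.
3. **Liver.** `I_liver = [I ≥ T4] ∧ ¬curve ∧ ¬I_cir ∧ ¬I_stm`, then ICM
   denoising, morphological opening (radius-`N_F` diamond), largest-component
   selection, Moore-neighbour boundary tracing and periodic smoothing-spline
   filtering `min (1−α)Σ|B_s−B|² + α∫|B_s''|²` with `α = 0.5`.
4. **3D.** Each boundary is resampled to 200 equal-arc-length points, start
   indices and orientations are aligned down the stack, each of the 200
   z-trajectories is smoothing-spline filtered, and the grid is exported as a
   watertight PLY/OBJ mesh.

A deterministic abdominal phantom (elliptical body, flank ribs, spine, liver
reaching the rib line, case-dependent adjacent organ, liver-equal-intensity
abdominal wall, Gaussian noise) provides ground truth for every stage, plus
cylinder/sphere stacks with analytic volumes.

## Worked example

```python
import numpy as np
from sddliver import PhantomSpec, generate_slice, process_slice, RunConfig, evaluate_masks

img, truth = generate_slice(PhantomSpec(case="stomach", seed=7))
result = process_slice(img, RunConfig())
print("thresholds:", result.thresholds.roles)
report = evaluate_masks(result.liver_mask, truth["liver"], spacing=1.0)
print(f"dice={report.dice:.3f}  VOE={report.voe_percent:.2f}%  "
      f"RVD={report.rvd_percent:+.2f}%  ASD={report.asd_mm:.2f} mm")
```

prints

```
thresholds: {'T1': 191, 'T2': 44, 'T3': 141, 'T4': 89}
dice=0.988  VOE=2.46%  RVD=+2.47%  ASD=0.59 mm
```

i.e. the detector found the four class-separating valleys (body at 44, liver at
89, stomach at 141, bone at 191 on the rescaled axis) and the constrained liver
mask overlaps the ground truth with Dice 0.988, a volumetric overlap error of
2.5 % and a mean surface distance of 0.6 mm at 1 mm pixel spacing.

The same stages are available from the shell:

```bash
sddliver phantom --case stomach --seed 7 --out work/phantom
sddliver segment --input work/phantom_imgs --out-masks work/masks --out-contours work/contours.csv
sddliver reconstruct --contours work/contours.csv --spacing 1.0,1.0 --out work/liver.ply
sddliver evaluate --pred work/masks --truth work/truth --out work/report.json
```

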