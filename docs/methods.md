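# Methods

## Overview

`sddliver` is a deterministic, training-free segmentation pipeline.  Its core
assumption is that an abdominal CT slice is a mixture of a small number of
intensity classes (air, soft tissue, liver-like parenchyma, a brighter adjacent
organ, bone) whose histogram valleys can be located automatically, and that the
structures segmented at the *other* thresholds (bones, body outline, adjacent
organ) carry enough geometry to isolate the liver even where neighbouring
tissue has exactly the liver's intensity.

## Threshold selection (slope difference distribution)

Intensities are affinely rescaled to {1,…,255} (`round(1 + 254·(v−min)/(max−min))`;
a constant slice maps to 255 everywhere and is flagged unsegmentable).  The
histogram is normalised by its *maximum* bin count — it is a shape signal, not
a probability distribution — and band-limited by zeroing all DFT coefficients
of the length-255 spectrum except the DC bin, the `W` lowest positive
frequencies and their conjugate mirror.  This is an orthogonal projection:
idempotent and mean-preserving.

At each intensity `i` in `1+N … 255−N` two ordinary-least-squares lines are
fitted, over `{i−N+1,…,i}` and `{i,…,i+N−1}`; for unit-spaced abscissae each
slope is a fixed linear functional of the window, so the whole signal
`s(i) = a_r(i) − a_l(i)` is computed by two sliding dot products.

A histogram valley (falling left arm, rising right arm) appears as a region of
*positive* `s` between two histogram modes; a mode appears as a negative dip.
Band limiting flattens wide valleys, which splits the single curvature peak
into two bumps at the valley shoulders, so valley candidates are not taken
directly from the raw `s`-maxima.  Instead:

1. modes of the smoothed histogram are detected (interior local maxima above
   `mode_min_height = 0.02` of the tallest mode, plateau-collapsed; the range
   edges count as modes when they dominate their inward neighbour — a class
   clipped at the rescaling boundary);
2. for every adjacent mode pair, the threshold is the `s`-weighted centroid of
   the positive part of `s` in the inter-mode interval (rounded).  For a sharp
   valley this reduces to the single `s`-maximum; for a flattened valley it
   stays centred between the shoulder bumps.  On an equal-weight two-Gaussian
   mixture (modes 80/180, σ = 12) this lands on the density intersection 130.
3. detections closer than `valley_merge_distance = 8` levels are merged,
   keeping the larger `s` (band-limited histograms ring slightly).

Positivity uses a floor of 1e-10 so float dust on flat histograms is not
mistaken for structure.  The detected threshold position changes monotonically
with the window `N`, which is what makes `(W, N)` calibratable; a grid-search
utility (`calibrate_params`) maximises mean end-to-end Dice over a labelled
set.  Defaults `W = 12`, `N = 20` resolve class modes ≥ 40 levels apart under
noise of σ ≈ 8 levels, and are exposed in the configuration.

### Threshold roles

Roles are assigned by rank: T2 (body/background split) is the lowest valley,
T1 (bones) the highest.  Among interior valleys, T4 (liver) is the valley
bounding the most-populated interior class from below — the liver is the
largest soft-tissue structure above the body class — and T3 (adjacent organ)
is the next valley up.  With three valleys T3 falls back to T1; with two,
T3 = T4 = T2 (a single soft-tissue class).  The organ constraint is only
built when T3 > T4; otherwise its mask cannot discriminate organ from liver
and the term is deactivated (an empty constraint is always legal).

## Denoising (Ising prior, ICM)

Binary masks are modelled with pairwise 4-neighbour cliques of potential −β
(equal labels) / +β (different), β = 1 by default.  Because the prior has no
data term its global optimum is uniform, so minimisation is deliberately
*local*: iterated conditional modes started from the observed mask, stopping
at the first full sweep without flips or after `max_sweeps = 20`.  Sweeps
update the two checkerboard half-lattices alternately; sites of one colour do
not neighbour each other, so each half-sweep is exact block coordinate descent
and energy never increases.  Ties keep the current label, hence every flip
strictly lowers energy and termination is guaranteed.  The converged mask
admits no energy-lowering single flip.

## Morphology

The structuring element is the radius-1 4-connected disk (5-pixel diamond);
`n` repetitions compose to the radius-`n` diamond (L1 ball), not a Euclidean
disk.  The filter (N_F = 8 erosions then dilations) is an opening that removes
any blob or attachment whose inscribed diamond radius is below N_F; the merge
(N_M = 16 dilations then erosions) is a closing that unites parts split by
gaps below ~2·N_M.  Outside the frame is background; the merge pads the frame
by N_M + 1 first so closing stays extensive at the border.  Blob labelling is
8-connected; structuring elements are 4-connected.

## Anatomical constraints

* **Rib curve.**  Bone blobs (binarised at T1, components below 8 px ignored)
  are split at the body-centroid column; blobs on the right *and around the
  centre* (within 5 % of the image width left of the split — the spine
  straddles the midline) are spine candidates, largest wins.  A least-squares
  quadratic `col = f(row)` through the rib + spine centroids separates the
  flank from the liver; the excluded half is the one *not* containing the body
  centroid.  (The spine centroid is itself a fit point and lies on the curve,
  so it cannot serve as the side reference.)
* **Ring.**  The body (binarised at T2, ICM-denoised, opened, hole-filled —
  it must be solid, since any interior hole would grow into a spurious ring
  under the erosion) minus its erosion by `N_c`, the mean rib width.  A rib's
  width is twice the maximal Euclidean distance of its pixels to background —
  the perpendicular stroke thickness for any orientation.
* **Adjacent organ.**  Binarise at T3 → ICM → subtract bones → open → keep
  components with centroid column beyond the spine centroid (after optional
  orientation flip for mirrored acquisitions) → close into one blob.

All three constraints are deterministic functions of (image, thresholds,
parameters); any of them may be empty, which simply deactivates its term.

## Liver rule, cleaning, boundary

A pixel is liver iff `I ≥ T4` and all three constraint masks are 0.  The raw
mask is ICM-denoised, opened with N_F, and reduced to its largest component
(ties broken by raster order; an empty mask raises a flagged "no liver found"
result rather than an exception).  The outer boundary is traced by
Moore-neighbour following (state = current pixel + backtrack pixel; the walk
terminates when the initial state recurs), oriented counter-clockwise in
(col,row) axes.

Boundary smoothing minimises `(1−α)·Σ|B_s(j)−B(j)|² + α·Σ|Δ²B_s(j)|²` per
coordinate with periodic second differences — the discrete fidelity +
integrated-squared-curvature objective.  `α = 0` is the exact identity;
`α` is clamped below 1 because the pure curvature objective collapses closed
curves.  The linear system `((1−α)I + αDᵀD)x = (1−α)y` is solved sparsely.

## 3D reconstruction

Each slice boundary is resampled to 200 vertices at equal arc length along the
closed polyline.  Orientations are unified by signed area and each contour is
cyclically shifted to the offset minimising the summed squared distance to the
previous aligned contour (brute force over the 200 shifts), so index `n`
traces a coherent z-curve without spiralling.  Physical coordinates are
`x = col·pixel_spacing`, `y = row·pixel_spacing`, `z = slice_index·slice_spacing`
(defaults 1 mm when headers carry no spacing).  Each of the 200 z-trajectories
is smoothed with the same discrete smoothing spline (natural boundary, per
coordinate); slices flagged empty are skipped at stacking and bridged by the
spline.  The grid becomes a consistently wound triangle mesh, periodic in the
in-slice index with optional centroid-fan caps (watertight; signed-volume
ready), written as ASCII PLY or OBJ.

## Evaluation metrics

Standard liver-challenge definitions: VOE = 100·(1 − |A∩B|/|A∪B|),
RVD = 100·(|A|−|B|)/|B|, and ASD/RMSD/MSSD as mean / RMS / max of the pooled
two-directional distances between *border voxels* (foreground with a
background 4-neighbour, background outside the frame), in mm under the given
spacings.  The border-voxel convention (rather than sub-voxel mesh surfaces)
is chosen for determinism and exact testability; it matches the voxel
resolution of the masks being compared.

## The phantom: what it emulates, what it does not

One 256×256 slice contains: an elliptical body (mean 60) on a dark background
(mean 25), five width-6 rib strokes along an inset (0.86) of the left body
ellipse plus a central posterior spine disk (mean 230), a liver (mean 120)
reaching the rib line (clipped at 0.84 of the body ellipse), a case-dependent
adjacent organ (mean 160) touching the liver's medial boundary — stomach,
kidney or heart placement — and an abdominal-wall band at exactly the liver's
intensity hugging the lower-left margin and touching the liver across the rib
line, plus i.i.d. Gaussian noise (σ = 8) clipped to [0,255].  The background
mean is chosen so the noise is not clipped into a single-bin spike, which
real CT air does not produce and whose spectral ringing would be an artefact
of the phantom rather than of the method.  In the raw liver-threshold mask the
wall and the liver form one connected component, so the rib-curve and ring
constraints — not intensity — are what separate them, mirroring the clinical
failure mode the pipeline exists for.

Stack mode replaces the liver with a disk whose radius follows a cylinder or
sphere profile along z, giving analytic reference volumes.

Not emulated: beam hardening, streaks, partial-volume ramps, anatomical shape
variability, multiple same-intensity organs on the organ side, contrast
agents.  Passing phantom tests therefore demonstrates the correctness of the
algorithms and the constraint geometry, not clinical-grade accuracy; on
clinical data the thresholds' accuracy dominates performance and `(W, N)`
generally need recalibration per dataset.

## Problem sizes and numerical choices

Tests and the acceptance script use 256×256 slices, 30 phantoms (10 per
adjacency case), 20 mixture trials, 30–33-slice stacks and 200-point contours;
these sizes make every quantity stable while keeping the whole suite fast on a
single CPU.  Exhaustive checks (all 2^16 4×4 masks for ICM optimality, full
pairwise surface distances) back the vectorised implementations.  Tolerances:
OLS agreement 1e-9; spline identity exact at α = 0; volume errors ≤ 2–3 %
against analytic solids (polygonal and slice-discretisation error); the
phantom-stack volume reconstruction carries an extra ~1 px rasterisation bias
of the traced boundary.

## Known limitations

* Threshold roles assume the liver is the most populated interior class; on
  slices where it is not (small caudal/cranial sections), T4 can bind to the
  wrong valley.  The per-slice structured log exposes the assignment.
* How an incoming slice's adjacency case should be *detected* is not defined
  by the method; the case is a configuration option and the constraint
  pipeline is identical across cases (only the phantom geometry differs).
* The curve constraint is a single quadratic: it cannot follow an S-shaped
  flank, and fewer than three usable bone centroids disable it (the pipeline
  falls back to a ring-only constraint).
* ICM is a local minimiser by design; it removes speckle, not structured
  artefacts.
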