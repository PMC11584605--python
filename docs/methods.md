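# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic phantoms do and do not emulate,
and the numerical choices made where the underlying methods left room.

## Conventions

Volumes are ZYX, 0-based, isotropic, with voxel centers at
`index · voxel_size_um + origin_um`. Anisotropic spacing is rejected rather
than resampled: resampling would smooth exactly the surface detail the
roughness score measures. All cross-module quantities are physical
(µm, mm, N, %); voxel counts never leave a module.

## Cartilage roughness score

**Surface extraction.** Within the condyle ROI the intensity histogram is
split by Otsu's threshold (overridable) and the largest connected tissue
component retained. Per (x, y) column the surface height is estimated from
partial-volume occupancy: with background level *b* and tissue level *f*
(class means), the topmost above-threshold voxel *k* and the voxel above it
contribute occupancies `(I − b)/(f − b)` each (clipped to [0, 1]), and

    z = (k − ½ + occ_k + occ_{k+1}) · h.

For a two-level partial-volume image this estimator is *exact*, whereas
midpoint interpolation between a saturated and a partial sample carries an
O(0.1 voxel) sawtooth bias that tilts plane fits on sloped surfaces. A
column quality rule rejects the ROI when more than 20 % of columns yield no
surface. With noise the occupancies become noisy rather than biased; the
default phantoms are noiseless because PTA-stained cartilage against air is
a very high-contrast boundary, and a `noise_sd` parameter exposes the
degradation (window-sized plane fits then inflate the null CRS — consistent
with intact joints scoring ~3° rather than 0° in practice).

**Local orientation.** The nominal neighborhood is 28 µm². At 4.5 µm voxels
that is smaller than two pixel footprints, so the centered square window is
expanded to the smallest size holding ≥ 6 valid nodes (a plane fit needs
3 non-collinear points; 6 gives slack against collinearity); the effective
base-window area is recorded on the surface. The fit solves the centered
2×2 normal equations per node, vectorized by box-filter moment sums; nodes
that stay degenerate after 8 expansions get NaN normals and are excluded
downstream.

**Reference surface.** Bivariate polynomial of total degree 5
(21 coefficients), fitted by least squares on coordinates centered and
scaled to [−1, 1]. Iteration: fit, compute residuals, drop
|residual| > k·SD (k = 2 default), refit; stop when the included set is
stable, the relative coefficient change < 1e−8, or 50 iterations. Symmetric
rejection down-weights both pits (lesions) and spikes (debris). An exact
model-class input terminates after one iteration via a zero-SD guard
(SD ≤ 1e−9 of the height scale). Non-convergence flags the result instead
of raising. At least 3× as many nodes as coefficients are required.

**Score.** θ = arccos(|n̂ₛ·n̂ᵣ|) folded to [0°, 90°] — the methods define no
sign for a deviation — with the reference normal evaluated analytically from
the polynomial gradient at the same (x, y). The CRS is the unweighted
arithmetic mean over valid nodes ("averaged over the whole condyle"); an
area-weighted option (weights 1/n̂_z) exists. Condyle ROIs are user-supplied
masks; automatic anatomy segmentation is out of scope.

## Bone morphometry

**Local thickness** follows the model-independent largest-inscribed-sphere
definition. Implementation: Euclidean distance transform gives each
foreground voxel its admissible sphere radius; sweeping the distinct radii
in descending order, a second distance transform to the current seed set
marks every voxel inside such a sphere, assigning the diameter on first
cover. Squared grid distances are integers, so cover tests are exact, and
the result provably equals exhaustive sphere enumeration (the test oracle
enumerates spheres by brute-force pairwise distances). Boundary convention:
beyond the array the structure continues (a slab spanning the field of view
is an infinite plate); phantoms therefore place the measurement ROI on
interior plates/gaps.

**Trabecular ROI** is the medullary mask eroded by a structuring element of
physical radius 315 µm, rounded to voxels; "circular" is read as a 2D disc
applied per coronal slice (the convention of slice-oriented tools), with a
3D ball behind a switch. Outside the array counts as background here —
the ROI retreats from volume borders. Erosion is set-identical to
thresholding the padded distance transform, which the tests assert.

**Metrics.** BV/TV is the exact count ratio; Tb.Th/Tb.Sp are the
volume-weighted means (plain voxel means of the thickness map) of the bone
and marrow phases inside the ROI — the standard model-independent
definitions. No bone in the ROI reports BV/TV = 0 with Tb.Th *missing*,
never 0. Plate/growth-plate delineation is an input, not computed.

## Synovial histomorphometry

The original macros are not public, so standard, fully parameterized
choices stand in: synovial thickness is the mean nearest distance from
points sampled every 1 µm along the lining contour to the fibrous-membrane
contour (direction choice matters only for strongly curved, non-parallel
contours; phantom symmetry under exchange holds to 1 %). Coincident
contours measure 0; crossing contours are an annotation error.

Cellularity: Ruifrok–Johnston H&E deconvolution, Gaussian smoothing
(1 µm), Otsu threshold with an absolute OD floor of 0.08 (so empty channels
never segment noise), distance-transform peaks ≥ 4 µm apart, watershed, and
a minimum nucleus area of 8 µm² — sized for rat synovial nuclei at ~1 µm
pixels. Collagen: trichrome deconvolution with in-package unit OD vectors
(scarlet ≈ [0.80, 0.59, 0.11], aniline blue ≈ [0.10, 0.74, 0.67]; exposed
in config) and a fixed aniline-blue OD threshold of 0.15 on region pixels.

Immunofluorescence classification anchors on Hoechst nuclei, samples each
marker as the mean intensity over the nucleus dilated by 1.5 µm, and
thresholds per channel by Otsu over the per-cell intensities with an
absolute floor of 0.15 (fixed per-channel overrides available; a
low-contrast channel is called uniformly negative/positive by the floor).
The four classes (CX3CR1+, CD68+CX3CR1−, double+, negative) are mutually
exclusive and exhaustive; the double-positive class is kept explicit so
counts always sum to the nuclei total. Lining vs sublining membership comes
from the user annotation polygons. Up to four ROI records are averaged
unweighted.

## Mechanics

Stiffness is the OLS slope of load vs displacement over the closed window
0.45–0.5 mm (a secant would be noise-sensitive; OLS uses every sample);
displacement zero is the recorded zero, with no toe-region re-zeroing.
Failure load is the curve maximum; peaks within 0.1 % of the load-cell
ceiling (50 N) are flagged censored and reported at the ceiling, not
dropped.

## Behavior

Per session the three runs with the lowest run-speed variation are kept
(stable sort; ties keep the first recorded). "Percent difference between
injected and contralateral, relative to baseline" is implemented as the
difference of within-day percent asymmetries, `d(t) − d(b)` — this makes
the baseline exactly 0 and gives negative values the "reduced weight
bearing" reading; a ratio-of-ratios variant sits behind `mode="ratio"`.
Duty cycle is `100·stand/(stand+swing)` per paw. PAM withdrawal forces are
percent of the day −7 baseline.

## Statistics

Group values are mean with t-based 95 % CI (point interval at n = 1; the
choice of t over normal quantiles is deliberate at the study's n = 3–4).
ANOVA (1–3 factors, full interactions) and Tukey HSD delegate to
statsmodels. Grader scores are averaged arithmetically; the rubric content
of Krenn/OARSI grading is human judgment and out of scope.

## Phantoms: what they emulate, and what they do not

All randomness flows through one seeded generator per phantom; identical
(parameters, seed) give bit-identical output, and ground truth is stored
beside the data.

* **Condyle**: cartilage band under `z = P₅ + a·sin(2πx/λ)·sin(2πy/λ)`,
  exact column partial volume, 4× in-plane supersampling; truth is the mean
  angular deviation from the base polynomial by gradient quadrature
  (default 600² nodes, stable to < 0.1 % under 10× refinement). The
  amplitude for a requested mean angle is found by bracketed root-finding
  on that quadrature. Bump wavelengths must exceed 4 voxels.
* **Plates / cylinders / rod lattices**: closed-form thickness, spacing and
  volume fractions (rod lattices by inclusion–exclusion including the
  tricylinder term). Plate ROIs cover whole interior periods so the closed
  forms are exact on the grid.
* **Histology / IF**: nuclei are dart-thrown with a minimum separation, so
  planted counts are unambiguous (the IF generator also keeps cells off the
  lining boundary); images are synthesized through the same stain-OD model
  the analyzers invert. Collagen masks are quantile-thresholded noise, so
  the planted pixel fraction is exact.
* **Load curves / gait cohorts**: linear-elastic ramp with a sampled peak
  and exponential post-failure drop; gait sessions plant the per-day deficit
  with a symmetric baseline and lay out run variations so the selected-run
  mean is controlled.

Not emulated: beam hardening, ring artifacts and PTA diffusion gradients in
µCT; stain variability, overlapping/touching nuclei and uneven illumination
in sections; viscoelastic toe regions in curves; inter-animal gait
variability structure. Passing the phantom round trips therefore validates
the *computational* chain — segmentation-parameter robustness on real
tissue still needs per-study checks, which is why every threshold is
exposed in configuration.

## Problem sizes

The test suite and the reproduction script use a 300×300-column condyle at
4.5 µm (≈ 171-slice volume) for the smooth null, 133×133 columns for the
planted-roughness recoveries, a 64²-lateral plate stack of four periods,
≤ 20³ masks for the exhaustive sphere oracle (20 seeds), 600×600 µm sections
at 1 µm pixels, and cohorts of four animals — sizes chosen so the full suite
runs in a few minutes on one CPU while every tolerance is met with margin.

## Known limitations

* The CRS is a height-field method: overhanging or vertical cartilage
  (steep condyle flanks) violates the single-valued assumption and must be
  excluded by the ROI.
* Thickness maps are voxel-quantized; sub-voxel structures (< 2 voxels)
  are unreliable, and even-diameter cylinders centered between voxels read
  ~1 voxel low.
* Stain vectors are fixed defaults, not estimated per slide; strongly
  different staining protocols require overriding them.
* Marker thresholds assume a bimodal or clearly one-sided intensity
  distribution per channel; dim, graded expression would need calibrated
  fixed thresholds.
* The deposited study scans are not distributed with the package; pipelines
  accept converted TIFF/NIfTI, and reproducing the printed group values
  requires downloading that collection.
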