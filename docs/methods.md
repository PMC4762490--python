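# Methods

This note documents the models, estimators and numerical choices behind
`cervidct`, and what the synthetic validation does and does not establish.

## Imaging model and units

Stacks are unsigned 8/16-bit intensity grids with an isotropic voxel size
in µm; axis 0 is the cross-section axis. Anisotropic voxels are rejected
rather than resampled — every morphometric formula below assumes a cubic
voxel, and silent resampling would change thickness statistics. All
physical quantities are converted once at ingest and carried in mm
(Tb.Th/Tb.Sp in mm, Tb.N/Tb.Pf in mm⁻¹), matching the units in which the
biomarkers are conventionally reported. TIFF is the interchange format
(multi-page or slice-per-file), with the voxel size stored both as a JSON
image description and as centimetre-based resolution tags; a raw
uint8/uint16 + JSON-sidecar path exists for scanner exports.

## VOI and segmentation

The volume of interest is an in-plane ellipse replicated across a slice
range (an elliptical prism). Placement is configuration-supplied — in the
original workflow the ellipse is positioned manually against the outermost
alveoli, and we deliberately do not invent an auto-placement heuristic. A
voxel belongs to the VOI when its centre lies inside the ellipse; the
descriptor volume is the exact π·a·b·N·t, not a voxel count. "Radius of
the minor/major axis" is read as the semi-axes: π·1.07·3.86 = 12.98 mm²
reproduces the quoted area, confirming the reading.

The global threshold is the arithmetic mean of the two dominant modes of
the VOI histogram. Mode finding: moving-average smoothing (window 5
levels for 8-bit, 257 for 16-bit), local maxima at least 20% of the
dtype range apart with prominence ≥ 5% of the smoothed maximum, the two
most prominent kept, plateau ties broken toward the extremes. None of
these constants is prescribed by the protocol being reproduced; they are
chosen so that a two-Gaussian histogram with peak separation ≥ 6 noise
SDs is always resolved, and all three are exposed in the configuration.
The threshold is carried at half-level precision (no rounding to an
integer gray level) and ties at the threshold go to bone (≥). For
rendered phantoms with bg/fg 20/200 and noise SD 10 this chain recovers
the generating structure with < 0.5% voxel error (asserted in tests).

## Biomarkers

**BV/TV** — foreground fraction of the VOI, in percent.

**Tb.Th / Tb.Sp** — model-independent local thickness
(largest-inscribed-sphere): every voxel of a phase is assigned the
diameter of the largest sphere fully contained in the phase that covers
it, and the index is the volume-weighted mean. Sphere radii are Euclidean
distance-transform values d (distance from a phase voxel centre to the
nearest off-phase voxel centre); because the true phase boundary lies
half a voxel beyond the last foreground centre, a sphere of EDT radius d
has diameter 2d − 1 voxels. Covering is resolved exactly: distinct radii
are swept in descending order, and one complementary distance transform
per radius marks the voxels covered at that radius. An exhaustive
brute-force sphere-fitting oracle (independent pairwise-distance code in
the test suite) matches the implementation voxel-for-voxel on random
structured volumes. Two boundary conventions matter:

* the VOI mask truncates spheres (structures cropped by the ellipse read
  thinner near its edge) — a bias shared with the workflow this
  reproduces, visible in the demo pipeline where both archetypes read
  ~0.02 mm thin inside a small ellipse;
* the image frame does *not* truncate (structures crossing it behave as
  extended), so full-frame phantoms measure like infinite plates/rods.
  The plate generator leads its pattern with half a gap so no slab butts
  against the frame.

Accuracy is one voxel: slabs an odd number of voxels thick are recovered
exactly, even ones read one voxel thin (no voxel centre sits on the
mid-plane sphere centre).

**Tb.N** — (BV/TV)/Tb.Th, the plate-model trabecular number, chosen over
test-line intersection counting because it is the convention of the
desktop micro-CT software this mirrors and yields the testable identity
Tb.N·(Tb.Th + Tb.Sp) = 1 on parallel-plate phantoms (held within 5%).
The choice is recorded in each profile's provenance tag.

**Surface estimates, SMI and Tb.Pf** — surfaces are triangulated by
marching cubes on the indicator field smoothed with a Gaussian of
σ = 1 voxel (level 0.5). Meshing the raw 0/1 field reproduces the
voxelization staircase and overestimates a sphere's area by ~10%; the
smoothed level set tracks the true boundary to well under 2% while moving
it less than a tenth of a voxel. Structures too small to survive
smoothing fall back to the raw field.

* SMI = 6·V·S′/S² with V the foreground voxel volume, S the mesh area,
  and S′ estimated by displacing every vertex one voxel along its outward
  normal and re-measuring the area (forward difference over Δr = 1
  voxel). Outward orientation is fixed by probing the field along the
  normals — one global sign suffices since mesh normals come from ±∇f.
  Calibration on voxelized ideals (radius/thickness ≥ 15 voxels): sphere
  4.12, rod 3.01, plates 0.00 — the residual +0.12 on the sphere is the
  finite-difference curvature bias (2R+Δr)/(2R), well inside the ±0.3
  acceptance band. A spherical cavity in a solid block scores strongly
  negative, as concave surfaces must (dilation shrinks them). Known
  limitation: vertex displacement does not merge surfaces, so gaps
  narrower than 2Δr are not closed; at the default one-voxel step and
  trabecular separations of ≥ 8 voxels this is negligible.
* Tb.Pf = (S₁ − S₂)/(V₁ − V₂), where state 2 is a true morphological
  dilation by a one-voxel Euclidean ball (restricted to the mask), with
  both surfaces meshed as above. Isolated convex bodies give positive
  values (≈ 2/R for a sphere); connected concave meshes give negative
  values because dilation closes their gaps.

## Synthetic data

The package's validation surface is synthetic by necessity — the original
scan corpus was never deposited. Three generators, all pure functions of
(parameters, seed):

* **Geometric phantoms.** Plates/rods/spheres voxelized by sampling the
  ideal geometry at voxel centres (no rounding of thickness to whole
  voxels: a 9.5-voxel slab alternates 9- and 10-voxel slabs, so fill
  fractions match the continuous ratio almost exactly). Preconditions
  (≥ 3-voxel plates, ≥ 5-voxel radii, 2-voxel margins) keep
  discretization error within the one-voxel contracts.
* **Trabecular phantom.** Gaussian-filtered white noise thresholded at
  the quantile giving the requested fill fraction: connected,
  sponge-like, exact BV/TV by construction, characteristic scale set by
  the filter σ (measured Tb.Th/Tb.Sp increase monotonically with it). At
  65% fill its SMI (≈ −3.5) and Tb.Pf (strongly negative) fall in the
  range reported for real antler trabecular tissue.
* **Cohort simulator.** Per species, biomarker vectors are drawn from a
  multivariate normal with the published corpus means and SDs (modern:
  17 red deer / 22 reindeer; archaeological: 23/27, shipped verbatim as
  package data). Inter-biomarker correlations were never published, so
  independence is the declared default and a 6×6 correlation matrix is an
  explicit, validated parameter. BV/TV is clipped to [0, 100] and
  nonnegative biomarkers are truncated at zero with a warning above 0.1%
  truncation (the archaeological BV/TV SD of 25.17 makes occasional
  truncation expected).

What passing tests on these data do **not** show: real antler is not a
stack of plates, its histogram peaks are broader and less symmetric, its
biomarkers are correlated, and archaeological material carries sediment
and diagenetic damage. The synthetic results validate the estimators and
the statistical machinery, not field performance.

## Statistics

Normality screening is Shapiro–Wilk at α = 0.05 per biomarker per species
(the protocol names only "a normality test"; Shapiro–Wilk is the standard
small-sample choice). Species comparisons are two-sided Wilcoxon
rank-sum (Mann–Whitney): exact null distribution when both groups have
≤ 25 observations and no ties, otherwise the normal approximation with
tie and continuity corrections; the two paths agree within 0.02 for
groups ≥ 15 and the exact path's type-I error is 0.05 ± 0.01 at the
study's group sizes over 10⁴ replicates (asserted). PCA standardizes by
default (the biomarkers mix %, mm, mm⁻¹); components are deterministic
with the largest-magnitude loading of each component made positive.

## Classification

Soft-margin SVM with Gaussian kernel on all six biomarkers, features
z-scored by default with the scaler fit on training rows only and refit
inside every LOOCV fold — the held-out sample never influences its own
fold (asserted by equivalence of LOOCV with explicit
train-without/predict). Label convention: h(x) > 0 ⇔ red deer
(alphabetically first group), recorded on every model. Hyperparameters
come from a grid of integer powers of two, c ∈ 2⁻⁵…2¹⁵ and
γ ∈ 2⁻¹⁵…2³ (the protocol says only "powers of both parameters"),
scored by LOOCV on the full training set; the chosen pair is then reused
for the reported LOOCV confusion matrix, mirroring the described
procedure rather than a nested CV (which would change the bias of the
estimate; the flag exists for callers who want it). Ties break toward
the smallest c, then the smallest γ. The grid search shares one libsvm
solver with the reference path but drives it through precomputed kernels
(per-fold scaled distances assembled from shared per-feature difference
matrices); a test pins both routes to identical accuracies. Variable
ranking is Guyon's SVM-RFE with the squared weights of a linear-kernel
fit on standardized features as the elimination criterion.

Confusion-matrix percentages are **truncated** (not rounded) to one
decimal, because that is the arithmetic the published tables use
(18/23 → 78.2, 21/22 → 95.4).

On cohorts simulated from the modern-corpus moments under the
independence default, grid-searched LOOCV reaches a median accuracy of
≈ 95% over 100 seeds — comfortably above the 82% observed on the real
corpus, as expected when biomarker correlations (which reduce effective
dimensionality) are absent. The acceptance bound is therefore one-sided
(median ≥ 82%). The modern→archaeological transfer failure reproduces
qualitatively (predictions collapse toward red deer); its exact 42% is
not reproducible without the real per-sample covariance and is asserted
as a trend only.

## Pipeline

The end-to-end run is deterministic given (config, inputs, seed); the
report embeds the canonical config and its SHA-256. Per-sample failures
become machine-readable exclusions (`read_error`, `geometry_error`,
`non_bimodal_histogram`, `morphometry_error`); operator annotations
(`excluded_fissure`, `excluded_sediment`) are honoured but never
auto-detected. The aggregate statistical stage runs only with ≥ 3
surviving samples and ≥ 2 per species. The demo generator renders
plate-phantom cohorts whose archetypes use each species' corpus-mean
thickness/separation (0.19/0.18 mm and 0.23/0.24 mm) with ±0.005 mm
per-sample jitter; with the default sizes the archetypes are separated by
far more than render noise, so demo LOOCV is 100%.

## Problem sizes

Validation fixtures are sized so the full suite runs on one CPU in a few
minutes: SMI calibration grids ≤ 100×80×80 at 15–20-voxel radii, oracle
comparisons on 22³ volumes over 10 seeds, 100-seed classification
simulation at the study's n = 39, 10⁴-replicate test calibrations. All
estimator accuracies quoted above are measured at these sizes by the test
suite itself.
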