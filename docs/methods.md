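# Methods

This note documents the models and numerical choices behind the package:
what each quality measure computes, which parameters matter, what the
synthetic phantom does and does not emulate, and where the design was
genuinely open.

## Preprocessing common to all measures

Every scan is first normalized so that the median intensity of near-pure
white matter (WM fraction > 0.9) equals 1. Tissue statistics use
per-class **medians** over near-pure voxels (fraction > 0.9) for
robustness to lesions and partial volume; means over the same voxels are
kept only for the CJV diagnostic, which is defined on means. The minimum
tissue contrast c_min = min(|m_GM − m_CSF|, |m_WM − m_GM|) is the unit in
which noise, inhomogeneity and edge slope are expressed; zero differences
are dropped and a scan with no positive contrast is unratable. For the
measures themselves, c_min is recomputed on the bias-corrected image:
under strong bias the class medians of the uncorrected image drift by
up to ~10 %, which would couple every contrast-normalized measure to the
bias level.

### Evaluation regions

- **WMe** (WM core): near-pure WM eroded by three 6-connected steps.
  The depth is set by two reach arguments: the 5³ local-SD window of the
  noise measure extends 2 voxels, and a 3 mm FWHM anatomical blur leaves
  an intensity deficit of ~0.02 (WM units) at depth 2 but only ~0.004 at
  depth 3. A shallower core lets partial-volume and smoothing ramps at
  the GM/WM boundary masquerade as noise and inhomogeneity.
- **Lesion exclusion**: voxels below the GM/WM midpoint shifted toward
  WM (m_WM − 0.5·(m_WM − m_GM)) are removed from the WM core — but only
  as 6-connected components of ≥ 27 voxels (≈ 27 mm³ at 1 mm). A
  pointwise threshold removes ~1.3 % of WM voxels at random at 9 % noise,
  riddling the mask with holes; coherent hypointense blobs (lesions,
  perivascular spaces) are what the exclusion is for.
- **CSFe** (CSF core): near-pure CSF eroded one step, keeping components
  of ≥ 27 voxels. Deeper erosion annihilates sulcal and thin ventricular
  CSF; when nothing survives, the noise measure falls back to WM alone
  and the report carries a `csfe-fallback` flag.
- **Boundary band**: the partial-volume GM/WM interface
  (0.25 ≤ WM fraction ≤ 0.75), minus anything 26-adjacent to CSF
  (fraction > 0.25). The CSF-adjacency rule stands in for the exclusion
  of extreme CSF/WM and vessel gradients.

## Noise (NCR)

The local standard deviation of the bias-corrected image is estimated in
5³ neighborhoods **restricted to the evaluation region**: the divisor is
the number of in-region voxels, and the estimate is rescaled by the
normal-theory small-sample factor 1/(c4(n)·√((n−1)/n)). Both choices are
load-bearing. Unrestricted windows mix boundary partial-volume ramps
into the estimate (a noiseless scan would not read ≈ 0), and without the
small-sample correction thin CSF regions — where windows contain ~10–30
voxels — read several percent low, which would make the min() over the
two regions jump when a segmentation error reshapes CSFe. NCR is the
smaller of the CSF-core and WM-core means, divided by c_min. In a pure
noise field this reduces to σ_noise/c_min, which is the closed form the
unit tests check.

## Inhomogeneity (ICR)

A Laplacian filter with Dirichlet boundary conditions is applied inside
WMe: interior voxels (all six neighbors in the mask) are repeatedly
replaced by the mean of their neighbors; the mask-boundary shell is held
fixed. Iteration stops when the largest update falls below 1e−4 of the
in-mask intensity range, or at 2000 iterations — the relaxation targets
the low-frequency field, and the cap bounds runtime. Two refinements
keep the measure from re-absorbing noise:

- the Dirichlet data are the in-mask 5³ local means of the observed
  boundary intensities, not the raw voxel values (the relaxed field
  follows its boundary data, so raw noisy values would re-inject exactly
  the variance the filter removes; ~3× ICR inflation at 9 % noise was
  measured with raw data);
- the SD is taken over a deep interior (three further erosions of WMe),
  because the harmonic extension of residual boundary noise decays over
  a few voxels.

ICR is that SD divided by c_min. It is reported and rated but excluded
from the composite.

## Bias field

The measure pipeline needs a bias-corrected image C_bc. The estimator
fits a low-order tensor-Legendre expansion (per-axis degree 3, total
degree ≤ 4) to the **log** intensity of the WM-core voxels by least
squares, exponentiates, and normalizes the field to mean 1 over the core
— the classic parametric (polynomial/DCT-style) smooth-field model. The
basis is too stiff to follow noise or anatomy but captures coil
sensitivity profiles essentially exactly on the phantom (r > 0.999
recovery; > 95 % reduction of WM intensity SD at 40–100 % bias). A
Gaussian-weighted extrapolation was evaluated first and rejected: with a
smoothing scale (15 mm) comparable to the WM core radius, the masked
average shrinks toward the core mean and recovers only ~12 % of the
field amplitude. On small grids the fit degree is reduced until there
are ≥ 20 voxels per basis function, and the log-field is clipped to ±2
before exponentiation; fields clipped at the 0.1 floor raise a flag.

## Resolution (RES) and edge sharpness (ECR)

RES is the RMS of the three voxel dimensions; the plain mean (RESM) is
kept as a diagnostic. RMS upweights a single coarse axis, matching the
preference for isotropic voxels. The anchors (0.5 mm best, 2.5 mm worst)
make each additional 0.5 mm cost exactly one grade.

RES is blind to data that were resampled or smoothed back onto a fine
grid. ECR closes that gap: central-difference gradients in per-mm units,
**projected onto the boundary normal** (the direction of the WM-fraction
gradient), averaged over the boundary band and divided by c_min. The
projection reads the slope *across* the interface; the unprojected
magnitude is positively biased by orthogonal noise gradients (+26 % at
9 % noise, measured), while the projected slope is first-order
noise-neutral. Without a segmentation the magnitude is used as a
fallback. Larger ECR = sharper anatomy, so its anchors are applied in
sharp-is-best orientation.

## Surface topology (FEC)

The WM fraction is resampled to 2 mm isotropic (linear), stabilized with
a 3³ maximum filter (thin WM structures in children otherwise break the
surface), and binarized at 0.25 and 0.75. Each binary volume is padded
by one background layer and triangulated marching-cubes style at level
0.5, so every surface is closed and χ = V − E + F is well-defined. A
clean genus-0 brain gives χ = 2 at both thresholds; the reported defect
is fec_raw = (|2 − χ₀.₂₅| + |2 − χ₀.₇₅|)/2, the only monotone
nonnegative reading consistent with larger-is-worse anchors. If the
0.75 surface is empty the 0.25 defect is used alone, flagged.

Because χ is a topological invariant, FEC is exactly invariant to
topology-preserving segmentation errors (e.g., uniform one-voxel
erosion of an ellipsoidal phantom class). Its sensitivity in real data
comes from thin structures breaking and speckle components appearing —
the behavior the speckle-planting tests exercise.

## Standardization and the composite

grade = clamp(1 + 4·(QM − BQM)/(WQM − BQM), 0.5, 10.5) maps each raw
measure through its anchors (NCR 0.0183/0.0868; ICR 0.2270/1.3949;
RES 0.5/2.5; ECR 0.1003/0.0202; FEC 130/470, overridable via a
plain-text config); rps = 105 − 10·grade clipped to [0, 100]; letters
label 10-rps bands with A+ reserved for the top quarter of the A band.
SIQR is the fourth-power mean of the NCR, RES, ECR and FEC grades —
symmetric, strictly increasing in each argument, and bounded between
the arithmetic mean and the maximum, so severe single-aspect problems
are not averaged away.

## Sample normalization (nSIQR) and ROC analysis

nSIQR = site Q75(rps) − scan rps, with Q75 by linear interpolation of
order statistics; sites with fewer than four scans use the maximum (a
quartile of 2–3 points is unstable, and the best score is conservative —
it never hides outliers). nSIQR is translation-invariant within a site
and is reported unclamped; > 5 rps flags a light and > 10 rps a strong
artifact suspect (configurable). ROC analysis uses the rank
(Mann–Whitney) AUC with ties counted ½; the decision threshold maximizes
Youden's J on one fold and accuracy is scored on the other, averaged
over the default odd/even 2-fold split. The reference thresholds
4.20/1.90/1.55 rps obtained on an external expert-rated motion dataset
are shipped as documented constants, not re-derived.

## The synthetic phantom

Geometry: nested ellipsoid shells — WM core (default radii 24/30/22 mm),
GM shell (3 mm), CSF shell (3 mm) — on a 96³ grid at 1 mm, with optional
sinusoidal folding of the WM boundary (default ±2 mm, 6 cycles) to give
the GM/WM interface gyrus-like orientation variety. Class intensities
0.2/0.6/1.0 (CSF/GM/WM) give a T1-like ordering and c_min = 0.4.
Partial-volume fractions come from 4× supersampling of the analytic
shapes with block averaging, so class volumes have closed-form oracles
(matched within 2 %) and WM topology is genus 0 by construction.

Perturbations, applied in acquisition order (anatomy blur → coil bias →
receiver noise → sampling grid):

- noise: additive Gaussian (or Rician magnitude) with SD = pct/100 of
  the WM intensity, the convention in which 1–9 % levels are specified;
- bias: three fixed low-order cosine field shapes (A/B/C) spanning
  exactly [1, 1 + pct/100] before mean-1 normalization over the brain,
  so the max/min ratio equals 1 + pct/100;
- smoothing: Gaussian with FWHM in mm, voxel-size aware;
- resolution: linear downsampling to a coarser grid, optionally linearly
  reinterpolated back to the native grid (the case a header-based
  resolution score cannot see);
- segmentation errors: erosion/dilation of a binarized class by
  6-connected steps, with displaced mass handed to the locally dominant
  neighbor class (or dropped to background at the outer brain skin), so
  per-voxel fraction sums stay valid.

Cohen's κ between segmentations uses hard labels (argmax, background
where all fractions < 0.5), per-class one-vs-rest κ = (p_o − p_e)/(1 − p_e),
and their mean over CSF/GM/WM, on the union of non-background voxels by
default. The bundled threshold re-segmentation maps intensity piecewise
linearly onto a continuous CSF=1/GM=2/WM=3 label and converts it to
partial-volume fractions; it has no spatial regularization, so per-voxel
noise shows up directly as misclassification — a deliberately simple
stand-in for a segmentation pipeline.

### What the phantom does not emulate

No skull, vasculature, anatomically realistic cortex, k-space motion
artifacts, or spatially correlated physiological noise. The GM/WM edge
is sharper than real cortex, so the edge-sharpness measure saturates at
its best grade on clean phantoms; the anchors were calibrated for real
anatomy and are kept at their published values rather than re-derived.
Passing tests therefore demonstrate the measures' contracts —
specificity, monotonicity, robustness, and the coupling between ratings
and segmentation overlap — not absolute agreement with any real-data
rating.

## Study conditions used by the test suite

The end-to-end tests use a 27-point lattice (noise 1/5/9 %, bias
20/60/100 %, smoothing 0/1.5/3 mm) on the default 96³ phantom with three
noise seeds; segmentation-robustness checks run at 3 % noise and 20 %
bias (a typical good scan); the outlier-detection experiment uses 40
clean (3 % noise) and 40 motion-proxy (5 % noise, the +2-percentage-point
equivalence) scans of a 64³ phantom in one protocol. Unit tests use 64³
or smaller grids. These sizes were chosen as the smallest at which the
masks, surfaces and statistics are comfortably away from their
small-sample regimes.

## Known limitations

- Anchors are fixed published constants; on synthetic data ECR and FEC
  often clamp at the best grade, so composite variation there is driven
  by NCR and RES.
- The NCR takes a min over two regions; when a segmentation error or
  fallback removes the CSF core, the measure switches regions, which
  bounds but does not eliminate its sensitivity to such errors
  (≈ 0.2 grade at 3 % noise in the robustness tests).
- The Laplace relaxation stop rule (1e−4 of range, cap 2000) is a
  runtime compromise; fully converged harmonic interpolation would
  differ slightly but monotonicity in bias is unaffected.
- FEC at 2 mm cannot detect defects finer than its resampled grid and is
  insensitive to noise when every speckle lies within the maximum
  filter's reach of the main surface (thin-GM geometries).
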