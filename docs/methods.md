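# Methods

`plaquefir` implements a label-free FTIR imaging analysis of
amyloid-beta (Aβ) plaques in brain gray matter, from hyperspectral cube
quality control through immunostain co-registration, compartment
masking and Amide I band analysis to cohort statistics, together with
a synthetic scene generator that provides ground truth for every stage.
This note documents the models, the numerical choices, and what the
synthetic conditions do and do not establish about real tissue data.

## Data model

A scene is an absorbance cube (rows × cols × channels) on a strictly
descending wavenumber axis, by default 3700 → 948.8 cm⁻¹ at 1.9 cm⁻¹
sampling (1449 channels) with 1.1 µm pixels — the geometry of a
focal-plane-array FTIR microscope in high-magnification transmission
mode. The axis is stored explicitly (HDF5 `/wavenumbers`) so
non-default instruments fit the same container. Canonical storage is
HDF5 (`/cube` float32, `/wavenumbers` float64, attribute
`pixel_size_um`); ENVI BSQ float32 with the wavelength list in the
text header, and two-column CSV for single spectra, are supported for
interchange. Pixel coordinates are 0-based (row, col); the spectral
cube is the reference frame for all registration.

## Quality control

Two per-pixel rules, applied before any averaging:

* **noise** — SNR ≥ 100, with SNR = (max absorbance in 1700–1600 cm⁻¹) /
  (std of the linearly detrended absorbance in 2000–1800 cm⁻¹). Both
  statistics use only in-spectrum information; the estimator is
  config-exposed because different operationalizations of "SNR" are in
  use across instruments.
* **scattering** — mean absorbance over the silent region
  (2300–1800 cm⁻¹) must not exceed A₁₆₅₅/2. Biological samples show no
  intrinsic absorbance in the silent region, so apparent absorbance
  there measures scattering contamination. The mean (not the max) is
  used as the silent-region statistic for robustness to noise spikes.

Excluded pixels are dropped from every downstream mean, never imputed.

## EMSC Mie-scattering correction

Each spectrum is decomposed by least squares as

y ≈ c·r + Σᵢ pᵢ·Lᵢ + Σⱼ mⱼ·Mⱼ

with r the reference spectrum (median over QC-valid pixels, normalized
to unit Amide I maximum), Lᵢ Legendre polynomials (order 2 by default),
and Mⱼ the first 7 principal components of a sampled family of van de
Hulst thin-sphere extinction curves Q(x) = 2 − (4/x)sin x +
(4/x²)(1 − cos x), x = 4πa(n−1)ν̃, over radii 2–12 µm and index excess
0.1–0.5. The corrected spectrum is (y − Σpᵢ Lᵢ − Σmⱼ Mⱼ)/c with c
floored at 10⁻⁶ (flagged); a singular design falls back to plain EMSC
without Mie terms (flagged). The fit runs over the full axis with no
excluded sub-regions; iterative resonant-Mie refinement with reference
updates is deliberately out of scope — the single-pass basis version
is sufficient for baselines in the van de Hulst family, and the
simulator draws its distortions from the same family, which makes the
correction-recovery property directly testable (silent-region residual
reduced ≥ 90 %).

Because the reference is unit-normalized, the multiplicative
coefficient absorbs per-pixel optical density; all downstream metrics
are band *ratios* and are unaffected by this normalization. Correction
is exactly idempotent (the residual is orthogonal to the design).

## Registration and ROIs

The immunostain (IHC) image is warped onto the cube grid — never the
reverse — by a 2×3 affine estimated from ≥ 3 user landmarks via least
squares; images at higher magnification are downsampled by the affine
itself. Warping is inverse-mapped bilinear interpolation with constant
background fill. Landmark geometry bounds: with k landmarks of
coordinate noise σ, the linear part is constrained by the landmark
spread while the translation error scales as σ/√k, so the reported RMS
residual (plus the simulated Dice checks) replaces visual overlay
verification. No residual threshold is hard-coded; the caller decides
what to accept.

## Masks and compartments

The plaque mask is Otsu's threshold (256-bin histogram) on the warped
IHC cutout, dark side positive (DAB polarity); thresholds are computed
per cutout, not globally. The *surrounding* compartment is the ring
0 < d ≤ 100 µm from the plaque mask by Euclidean distance transform —
distance from the mask boundary, not the centroid, which is the correct
reading of radial thickness for non-circular plaques — minus all
Otsu-positive pixels (same threshold as the plaque mask by default).
Mean spectra are arithmetic means over mask ∩ QC-valid pixels.

## Core segmentation

For classic cored plaques, QC-valid cutout spectra restricted to
1800–1000 cm⁻¹ and L2-normalized are clustered by agglomerative HCA
(Ward linkage, Euclidean metric — the standard chemometric choice,
config-exposed) and cut at k = 10. Above 20 000 pixels a deterministic
subsample is clustered and labels propagate by nearest centroid.
Segmentation runs on a tight plaque cutout (plaque bounding box + 8 px)
rather than the wide ring cutout, since Ward linkage is quadratic in
pixel count.

Core selection automates what is otherwise an expert visual merge:
clusters are ranked by the beta-sheet ratio of their mean spectrum;
those exceeding the surrounding-tissue cluster (the cluster with the
most pixels outside the plaque mask) by a margin of 1.0 — chosen to sit
between the corona's contrast (~+0.5) and the core's (~+2.5) on
default scenes — and overlapping the plaque mask are merged. Ties
within numerical tolerance merge inclusively. Connected components
smaller than 5 pixels are discarded; an empty core is a legal outcome
(it is the expected outcome for diffuse plaques). An explicit cluster
list reproduces manual selection.

## Amide analysis

* Linear baselines anchor on the single channels nearest the window
  endpoints (1800–1480 cm⁻¹ for the Amide region, 1690–1610 cm⁻¹ for
  the beta band), the simplest consistent reading of an endpoint
  baseline.
* Area normalization divides by the rectangle-rule integral of |A| over
  1690–1610 cm⁻¹. The beta-mode difference of two normalized spectra
  integrates to exactly zero when both baselined segments are
  non-negative; realistic segments can dip marginally below the
  endpoint chord, so the cancellation is near-exact (≲10⁻³) rather
  than machine-exact in general.
* Second derivatives are Savitzky–Golay, polynomial order 3, window 5,
  per (cm⁻¹)²; the two channels at each edge, where the window would
  truncate, are NaN.
* Band heights are local extrema within ±5 cm⁻¹ of the nominal
  position (the 1.9 cm⁻¹ grid does not contain 1630 or 1628 exactly);
  positions are refined by parabolic interpolation through the
  extremum and its neighbours. Heights are read at the grid extremum,
  unrefined. A pick whose extremum falls on the window boundary is
  flagged unresolved.
* Ratios: protein ratio = Amide II height (1545) / mean CH-stretch
  absorbance (3000–2800), both on the corrected, non-baselined
  spectrum (a peak-based CH statistic is config-exposed); beta ratio =
  h(1630)/h(1655) on the baselined Amide segment; d2 height difference
  = d²A at the 1628 pick minus d²A at the 1693 pick (not scale-free by
  construction). Denominators are floored at 10⁻⁶ with a flag.
* Per-pixel ratio maps use vectorized window maxima (no sub-grid
  refinement — maps report heights), mirroring the plaque-spectrum
  treatment (raw for protein, baselined for beta); QC-invalid pixels
  are NaN.

## Statistics

Groups are ordered control → diffuse → compact → classic cored → core.
Adjacent pairs are compared with the classical pooled-variance
two-sample Student's t-test (Welch and all-pairs variants are flags),
two-sided, uncorrected for multiplicity; stars at p < 0.05/0.01/0.001.
The protein–beta correlation is the Pearson R over plaque and core
spectra only (controls excluded). Boxplot summaries use
linear-interpolation quartiles and the 1.5·IQR outlier rule. A
leave-one-case-out median-shift summary is available as a
case-influence check.

## Synthetic scenes

The generator emulates gray matter with Aβ deposits as sums of
Gaussian bands (Gaussian rather than Voigt shapes keep the analytic
band mathematics tractable in tests; widths are chosen so neighbouring
Amide I sub-bands genuinely overlap and second-derivative picking does
real work):

* **Gray matter** — composite Amide I: 1655 (σ 13, 0.40) with minor
  sub-bands 1693 (0.075), 1682 (0.045), 1657 (0.03), 1639 (0.05);
  Amide II 1545 (0.25); ester 1738 (0.10); CH stretches at 2852, 2872,
  2925, 2958; broad N–H/O–H at 3290. The sub-band structure makes
  control-tissue second derivatives resolve the same band set as
  plaques, and produces the localized negative ~1694 feature when a
  fibrillar core is differenced against its surround.
* **Oligomer component** — main β band 1630 (σ 6.0, 0.65), antiparallel
  marker 1693 fixed at 8 % of the main band, weak turn 1682, disordered
  1655 content, Amide II 0.45. The main band is weaker than the
  fibril's (oligomers carry less β-sheet per protein) and narrow
  enough that the beta-mode difference spectrum of an
  oligomer-dominated deposit, after endpoint baselining and area
  normalization against the surround, peaks at 1630 cm⁻¹.
* **Fibril component** — main band 1628 (σ 7.0, 1.00) with a shoulder
  at 1618 raising absorbance around 1620, turn band 1683 (0.25), no
  1693 marker. The narrower, stronger main band gives fibrils a deeper
  second-derivative minimum than oligomers, so the d2 height
  difference trends more negative with fibril fraction.
* **Morphologies** — diffuse: low density, oligomer-dominated,
  blob-like scatter (smoothed random field inside a soft disk);
  compact: intermediate, centralized (default) or homogeneous; classic
  cored: corona plus a dense fibril-dominated core (density ~2.0,
  fibril fraction ~0.92) whose ester band is scaled to 0.35 — reduced
  but strictly positive, representing residual lipid in cores.
* **Per-plaque draws** — (density scale, fibril fraction) come from
  per-type priors through a bivariate Gaussian copula; cored plaques
  draw corona and core parameters from the same latent pair. Each
  plaque also draws an Amide II admixture factor (sd 0.19) modelling
  variable non-amyloid protein content (dystrophic neurites, glial
  material). Gray-matter composition varies across the scene through
  smooth multiplicative protein (sd 0.28) and lipid (sd 0.42) fields
  with ~13 µm correlation length — control tissue is not homogeneous.
* **Distortions** — per-pixel van de Hulst Mie baselines (the same
  family the EMSC basis spans), i.i.d. Gaussian noise (σ 0.001 AU), and
  a configurable fraction (default 2 %) of deliberately low-SNR pixels
  that define the QC ground truth. The silent region carries no band
  absorbance by construction, so any apparent absorbance there is
  attributable to the Mie term exactly.
* **Pseudo-IHC** — stain uptake saturates with density (Hill-type,
  half-saturation 0.08), intensity decreases monotonically with
  density (dark = positive), with optional glial gaps and hollow-core
  rendering; the image is produced at 2× magnification under a known
  misalignment affine (3° rotation plus translation), which is also the
  source of exact landmark pairs.

One global seed drives every draw; identical seeds give bit-identical
scenes. Aβ density is in arbitrary units by design — no quantitative
concentration scale is asserted.

### Calibration of the default coupling

The copula correlation is the packaged dial linking plaque density to
fibril fraction. The dispersion defaults (heterogeneity field
amplitudes, Amide II admixture sd, copula ρ = +0.60 — denser plaques
more fibrillar) were fixed in a single development-time calibration so
that the full pipeline's pooled Pearson R between the protein and
beta-sheet ratios on the default cohort (ten 150×150 px scenes of
4+4+4 plaques) reproduces the R = 0.73 reported for human AD plaque
cohorts; they have not been revisited since.
Measured over four independent ten-seed batches the pooled R was
0.745/0.713/0.700/0.747.

### What the synthetic conditions do not show

The generator reproduces the *statistical structure* the analysis
assumes — band composition, compartment geometry, scattering family,
noise — not real tissue. Gaussian bands have no rotational–vibrational
fine structure; Mie distortion is non-resonant (no dispersive band
shapes); the pseudo-IHC has no colour chemistry, no section folds or
tears, and the misalignment is exactly affine; no white-matter,
vascular amyloid, or tau co-pathology is modelled. Passing tests
establish that the pipeline recovers known ground truth under these
conditions, not that it is robust to artifacts outside them.

## Problem sizes

Defaults keep everything single-CPU friendly: single-plaque scenes are
64×64 px (a few seconds through the full chain), cohort scenes 150×150
px with 12 plaques (~20 s each), and the statistics cohort uses ten
seeds (~150 plaques plus cores). HCA is run on tight plaque cutouts
(≤ a few thousand pixels); the 20 000-pixel subsampling cap exists for
larger cutouts.

## Known limitations

* The automated core-selection margin is calibrated to the default
  band contrasts; tissue with weaker core/corona contrast may need the
  margin lowered or manual cluster selection.
* The SNR and silent-region estimators are one reasonable
  operationalization among several; both are config-exposed.
* Single-pass EMSC does not model resonant Mie dispersion.
* Pooled-variance t-tests inherit the usual caveats under unequal
  variances (a Welch flag exists) and no case-level clustering is
  modelled.
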