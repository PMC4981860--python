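# Methods

This note documents the models and conventions implemented in
`hepatexture`, the defaults chosen where a convention had to be fixed, and
what the synthetic phantoms do and do not demonstrate.

## Windowing and geometry

Each MR slice is converted to a numerical matrix inside an intensity
window `[window_min, window_max]`: bounds are taken from the DICOM
WindowCenter/WindowWidth when present, otherwise from the slice min/max,
and pixels are clipped into the window on load (clipping is idempotent).
The pipeline then rescales pixels to the dimensionless `[0, 1]` window
range before estimation (configurable), which makes the estimators
comparable across scanners and protocols and gives the mode (E6) the 0–1
scale that the FibroMRI coefficient magnitude (−115.737) presupposes.

Pixel coordinates are row-major and 0-based with (0, 0) at top-left.
Pixel spacing is field-of-view divided by matrix size, per axis.

Protocols are identified by case-insensitive substring matching of the
DICOM SeriesDescription against a configurable alias table
(`ssfse`, `stir`, `phase`, `dyn` by default); unmatched series load as
UNKNOWN and are excluded from scoring. Only single-frame files are
supported; enhanced multi-frame DICOM is out of scope. Where a dynamic
acquisition has several phases, the alias table should be pointed at the
one series to use — the reader does not collapse phases.

## Grid sampling

A sampling grid of side *k* pixels is anchored at pixel (0, 0) of the
image (a fixed anchor makes runs reproducible; the anchor is not a
published convention). The side is chosen so one square corresponds to
the midpoint of a 15–24 mm³ target tissue volume:

    k = round( sqrt(V_mid / thickness) / pixel_spacing ),  clipped to [10, 23] px

using the mean of the row/column pixel spacings. At typical 1.5 T body
matrix/FoV combinations (≈ 1.5 mm spacing, 5–7 mm slices) the formula
lands below 10 px and the clip dominates; the printed 10–23 px range is
treated as the authoritative operational constraint because the volume
target and the pixel range cannot both hold at such spacings. Only
complete squares are formed (a partial last row/column is dropped), so
squares never overlap and each in-mask pixel belongs to at most one
sample.

A square's `inside_fraction` is the fraction of its pixels whose centres
lie inside the rasterized contour polygon (even–odd rule, boundary pixels
included). The parenchyma rule is strict and exact: a square passes iff
`10·n_inside ≥ 7·k²`, evaluated on integer counts, so a square with
exactly 70 % of pixels inside passes and 69.99 % fails.

## Homogeneity quality control

Samples containing vessels, ducts or other non-parenchymal structures are
rejected automatically: a pixel is an outlier when its deviation from the
sample median exceeds `z_cut` (default 3.0) robust standard deviations,
and the sample is flagged INHOMOGENEOUS when the outlier fraction exceeds
`f_cut` (default 5 %). Manual reject lists are honoured with reason
MANUAL.

The robust scale is 1.4826 × MAD. By default it is estimated from the
sample itself, but the pipeline estimates it from **all in-contour pixels
of the slice**: a vessel crossing more than about a fifth of a single
square inflates that square's own MAD enough to mask the vessel, whereas
the parenchyma noise level is a stable slice property (vessels are a
small fraction of the whole liver section). On phantom ground truth the
slice-level scale detects every grid square with ≥ 10 % vessel coverage
while flagging no clean interior squares; the sample-level fallback
detects isolated stripes (the 10 %-at-−6 SD case) but misses heavily
crossed squares.

## The estimator registry

Each passing sample is summarised by 84 estimators, E1–E84, organised as:
E1–E30 first-order statistics, E31–E60 co-occurrence features, E61–E80
intensity-surface geometry, E81–E84 spectral descriptors. Seven ids carry
published meanings and are frozen: E3 harmonic mean, E6 mode, E22
Pearson's asymmetry coefficient, E31 column marginal mean of the
multi-oriented co-occurrence matrix, E57 second-order contrast, E73
averaged mean curvature, E75 maximum principal curvature. The remaining
77 are registry fillers — standard descriptors of each family chosen by
this package, declared as such in the versioned manifest
(`registry_manifest()`); they exercise the computation path and are
available for refitting, but no published coefficient attaches to them.
Changing any definition bumps the registry version.

Conventions that had to be fixed:

* **Quantization**: 16 equal-width gray levels over the context value
  range (the window). Estimators of differences (contrast, skewness,
  curvature) are then invariant to adding a constant to all pixels, as
  long as intensities stay away from the window edges.
* **Co-occurrence**: distance 1, four orientations with displacement
  vectors (0,+1), (+1,+1), (+1,0), (+1,−1), symmetric accumulation,
  per-orientation normalisation; "multi-oriented" means the element-wise
  mean of the four matrices. These are the standard Haralick conventions;
  all are configurable. Degenerate (constant) textures define
  co-occurrence correlation as 1.
* **Pearson's asymmetry** (E22) is the second coefficient,
  3(mean − median)/sd with the population sd; the first coefficient needs
  the mode, which is unstable on 100-pixel samples. A constant sample
  yields 0 by convention.
* **Mode** (E6) is the lower edge of the modal quantization bin, ties
  broken toward the smaller bin.
* **Harmonic/geometric mean guard**: when a sample contains non-positive
  values the pixels are shifted by one quantization step before the mean
  (configurable); if values remain non-positive the estimator is recorded
  as missing rather than aborting the vector.
* **Curvature**: intensity is a height field z = s·I with
  s = 1/(window range) by default so the geometry is window-invariant.
  Derivatives are central differences on an edge-replicated grid; mean
  curvature H, Gaussian curvature K and principal curvatures k1 ≥ k2
  follow the standard Monge-patch formulas, and summary statistics use
  interior pixels (one-pixel border excluded). Edge replication bends the
  surface within two pixels of the border — a planar ramp has exactly
  zero H only in the 2-px interior — which is accepted as a boundary
  effect of the stencil.
* **Spectral**: 2-D FFT power with the DC term excluded; band fractions
  over normalised radial frequency r < 1/6, 1/6 ≤ r < 1/3, r ≥ 1/3, plus
  the Shannon entropy of the normalised power spectrum. A constant sample
  reports 0 for all four.

Missing estimator values carry a reason and are excluded pairwise when
per-sample vectors are averaged into the patient × protocol aggregate; an
estimator missing from every sample stays missing, and a missing feature
required by a scoring model is an explicit error — no imputation.

## Biomarker models

A biomarker is a logistic model over per-protocol estimator aggregates;
patients are called positive when p > threshold **strictly** (threshold
0.5 for both presets). Patients are scored on aggregated estimators
(aggregate-then-score); scoring per sample and averaging probabilities is
available behind a switch but is not the default, since the original
modelling relates per-sample parameters to patient outcome through a
single regression.

The published slopes are stored verbatim. Open issues handled explicitly:

* Intercepts were never printed: presets carry `intercept = 0` flagged
  `intercept_free`; `with_intercept()` produces a calibrated model.
  Until calibrated, probabilities are only rank-meaningful.
* NASHMRI names three estimators but prints two slopes; the preset maps
  0.079 → E3 (SSFSE-T2) and 0.127 → E57 (DYNAMIC) and ships the E73
  (FAST-STIR) slot with coefficient 0, flagged incomplete.
* The printed odds ratio 0.08 for the mode coefficient −115.737 is
  inconsistent with OR = exp(β); the coefficient is kept verbatim and the
  mode must be fed on the 0–1 normalised scale (which the pipeline does).

Refitting uses the deterministic Newton solver of statsmodels with Wald
tests and exp(β) odds ratios; perfect separation is flagged (BFGS
fallback) rather than fatal, and rank-deficient designs are rejected.
Forward selection enters terms by likelihood-ratio test at p < 0.05; the
raw LR p of the best remaining candidate is Bonferroni-multiplied by the
pool size by default, so the chance of any noise variable entering stays
near the nominal level regardless of how many candidates are screened
(`adjust=None` restores the classical unadjusted procedure).

## ROC statistics

AUROC is the tie-corrected Mann–Whitney statistic; its standard error is
the Hanley closed form with Q1 = A/(2−A), Q2 = 2A²/(1+A), and the 95 % CI
is A ± 1.96·SE clipped to [0, 1]. Two curves are compared by
z = (A₁−A₂)/√(SE₁² + SE₂² − 2r·SE₁·SE₂); for paired designs r is the
average of the two within-class Pearson correlations between the score
vectors (used directly as the AUROC correlation — a linear approximation
to the tabulated adjustment), and r = 0 for unpaired designs. Simulations
under the negative-exponential ROC model (the model underlying the SE
formula) show the unpaired test rejects at 5 % ± 1 % under the null.

Threshold metrics use the same strict score > threshold rule as the
models; PPV/NPV are reported as missing when their denominator is empty.
The Youden-optimal cut-off scans midpoints between adjacent distinct
scores, breaking ties toward the threshold nearest 0.5.

The sample-size calculator returns the smallest total n (split by
prevalence) for which the two-sided z-test on the AUROC difference
reaches the target power under Hanley SEs with r = 0. Treating the curves
as uncorrelated is conservative for paired designs: for AUROCs 0.83
vs 0.95 at α = 0.05, power 0.80, prevalence 0.5 it yields n = 122,
larger than published figures computed under (unstated) positive
correlation assumptions. Simulated power at the returned n is ≈ 0.83.

## The phantom generator

Phantoms emulate the *statistical texture* of axial liver MR — not MR
physics (no k-space, relaxation or coil models). Per slice, a
liver-shaped mask (two overlapping ellipses minus a notch, shrinking 25 %
toward the stack ends) is filled with

    base + bias_amp · smooth_field(scale) + noise_sd · skew_normal(skew)

plus dark vessel tubes (random walks of configurable width/length at
−6·noise_sd contrast) and a dark background, quantized to integers in a
fixed [0, 1023] window and written as genuine DICOM files. Contours are
marching-squares outlines of the mask, sub-sampled 3:1. Each texture dial
moves one estimator family monotonically: noise → E57, skewness → E22,
bias field → E73/E75, base level → E3/E6. Vessel masks are emitted as
ground truth for QC validation.

Default study conditions: two cohorts of 20 + 20 patients, 96×96 matrix,
360 mm FoV, 7 mm slices, 3 slices per protocol, three protocols
(SSFSE-T2, FAST-STIR, DYNAMIC — the ones the presets consume). The
separated-class cohort gives the disease class a higher base level
(480 → 600), noisier (SD 15 → 45), more skewed (0 → 2) and more strongly
biased (10 → 35) texture, so both NASHMRI slopes point in the disease
direction; the null cohort uses one shared intermediate texture. These
sizes keep a full two-cohort run around half a minute on one CPU while
leaving patient-level feature noise well below the class separation.
Generation is a pure function of (spec, class, patient index) via
`SeedSequence([seed, class, index])` substreams, so cohorts of any size
are reproducible patient by patient.

What phantom results do **not** show: robustness to anatomy (organ shape
variation, partial-volume effects at real boundaries), scanner effects
(coil shading beyond smooth bias, reconstruction filters), or the actual
clinical effect sizes — the class separations here are synthetic choices,
so a phantom AUROC of 1.0 validates the pipeline's plumbing and ranking
behaviour, not clinical accuracy. Clinical performance claims require the
original cohorts, which are not publicly deposited.

## Known limitations

* The 77 unnamed registry estimators are this package's own definitions;
  published per-estimator values (beyond the seven named ids) cannot be
  reproduced because their original formulas are not public.
* Preset probabilities are uncalibrated (free intercepts); only rankings
  are directly usable out of the box.
* The correlated-AUROC r uses the within-class score correlation
  directly; DeLong's variance estimator is deliberately not implemented
  (the Hanley machinery is the published method here).
* No automatic liver segmentation: contours are inputs.
* One frame per DICOM file; no PACS transport; no 3-D (through-slice)
  texture.
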