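# Methods

## Scope and data model

All maps and masks are 3D scalar or boolean grids with physical voxel
spacing and RAS-style axis codes (`VolumeImage`, `BinaryMask`); DSC
acquisitions are 4D `DynamicSeries` with TR, TE and the pre-bolus injection
delay. Inputs are assumed co-registered: the package provides only grid
resampling (trilinear for maps, nearest for masks, through the NIfTI
affines), not registration estimation. Mask algebra requires identical
geometry (same dimensions, spacing within 1e-6 mm) and fails loudly
otherwise — silent resampling is forbidden. The reference grid for a case is
the FLT PET grid; the "contralateral side" of any ROI is its reflection
about the mid-sagittal plane (index `i → N−1−i` along the left–right axis).

## DSC-MRI perfusion

Signal is converted to the change in transverse relaxation rate
`ΔR2*(t) = −ln(S(t)/S₀)/TE` (ms⁻¹), with S₀ the per-voxel mean over the
baseline frames: all frames fully acquired before the injection delay,
discarding the first frame as a steady-state transient, minimum three.
Voxels with S₀ ≤ 0 or outside the brain mask are flagged invalid and never
enter statistics.

Each voxel's first pass is fitted with the standard γ-variate bolus model
`c(t) = K·(t−t₀)^α·exp(−(t−t₀)/β)` (zero before t₀). The fit window runs
from just before bolus arrival (first sample exceeding 10% of peak) to the
first post-peak sample below 20% of peak, excluding recirculation.
Initialisation is by log-linearisation of the model on the rising edge;
optimisation is trust-region least squares on `(ln K, t₀, ln α, ln β)`
(positivity by construction), tolerances 1e-12, up to 3 jittered restarts.
CBV is the area under the fitted curve, taken from the closed form
`K·β^(α+1)·Γ(α+1)`; numerical integration of the fitted curve is available
and agrees to ≤1e-6 relative. Failed or sub-noise-floor fits yield CBV 0
with a QC count — never NaN — so downstream thresholding always sees finite
maps. Identical curves are fitted once (a large saving on noise-free
phantoms). rCBV divides CBV by its mean over the normal-appearing
contralateral ROI: the mirrored tumor hemisphere intersected with brain,
minus the mirrored FLAIR hypersignal.

Identifiability: with TR 2.28 s, boluses narrower than about 1.5 samples
(αβ ≲ 3.5 s) are not uniquely recoverable from noise-free samples; the
randomized fidelity checks therefore draw α ∈ [2.5, 5], β ∈ [1.4, 3] s,
within the physiological first-pass range.

## Segmentation

* **Statistical contralateral threshold** (`Mean Contra + k·SD`): mean and
  sample SD (ddof 1) over the contralateral ROI; voxels strictly above
  mean + k·sd are selected, optionally intersected with the FLAIR
  hypersignal. With Gaussian background the selected healthy fraction is the
  upper tail Φ̄(k): 2.5% at k = 1.96 (rCBV), 4.83e-4 at k = 3.3 (FMISO) —
  the calibration the thresholds rely on, verified by Monte Carlo.
* **Percent-of-max**: threshold = fraction × max over the search ROI, `≥`
  rule (40% of SUVmax for FLT comparison).
* **Reference ratio**: strictly above factor × reference (1.2
  tissue-to-blood for FMISO; 2–3× the NAWM mean for CBV).
* **FLAB**: the original fuzzy locally adaptive Bayesian algorithm is not
  printed in the source literature we target behaviorally, so the
  implementation is an iterative Bayesian estimator on 2 or 3 Gaussian
  intensity classes augmented with fuzzy transition levels (mixed voxels at
  class interfaces, means/variances interpolated between the adjacent pure
  classes), followed by a locally adaptive relabelling pass that uses the
  3×3×3-neighborhood class composition as a spatial prior. The tumor mask is
  the highest-mean class. Acceptance is behavioral: Dice ≥ 0.95 against
  truth on well-separated two-class phantoms and Dice ≥ 0.9 agreement with
  the Mean Contra + 3.3 SD mask. Constant-intensity ROIs are a hard error,
  not an arbitrary split. The default operator ROI is the FLAIR bounding box
  dilated by 2 voxels.
* **Hot spot**: voxels at or above the 95th percentile (linear interpolation
  between order statistics) of the map within the FLAIR hypersignal; always
  a subset of FLAIR.

Strictness convention: statistical/ratio thresholds use `>`, percentile and
percent-of-max use `≥`, so a constant FLAIR region yields a full — not
empty — hot spot. Non-finite voxels are excluded from statistics and never
selected. Every `SegmentationResult` records its realized threshold and
parameters, so each mask is reproducible from its own metadata.

## Peripheral metrics

`peripheral_volume_pct(A, CE) = 100·|A AND NOT CE| / |CE|` on voxel counts
of the shared grid (exact integer arithmetic; mL volumes reported
alongside). The denominator is deliberately the CE volume, so values exceed
100% when a modality extends far beyond enhancement. An empty CE mask is a
hard error. Cohort summaries bin peripheral volumes at 0–20%, 20–40%, >40%.

## Synthetic phantom

The generator emulates the acquisition geometry of a 1.5-T DSC protocol and
a clinical PET reconstruction: default grid 48×48×14 at 2.19×2.19×7 mm, DSC
with 35 frames, TR 2.28 s, TE 60 ms, 20 s injection delay; PET-like spacing
(1.95×1.95×3.27 mm) is available through the config. All modalities share
one grid by default so truth bookkeeping is exact under mask algebra.

Anatomy is deliberately schematic: an ellipsoidal brain split into
hemispheres, with a tumor of three nested spheres voxelized by
center-of-voxel inclusion (analytic volumes available for tests) — necrotic
core (8 mm), enhancing rim (14 mm), infiltrative margin (17 mm). CE defaults
to the rim shell; FLAIR hypersignal to core ∪ rim ∪ margin. The radii were
chosen so the truth peripheral volumes fall in the clinically observed
range (FLT ≈ 141%, FMISO ≈ 24%).

SUV maps are compartment means plus Gaussian noise (FLT: background 0.4,
rim 2.2, margin 2.1, core 0.5, SD 0.08 — proliferation persisting through
the infiltrative margin; FMISO: background 1.0 with the large SD 0.18
characteristic of the tracer, rim 1.9, core 2.0, margin 1.1), optionally
convolved with a Gaussian PSF (FWHM in mm, applied before noise: resolution
then counting noise). The DSC series is the exact forward model
`S(t) = S₀·exp(−TE·ΔR2*(t))` with per-compartment γ-variate curves; the rim
bolus area is 3× background (hypervascular), the core 0.3× (necrotic),
the margin 1×. DSC noise defaults to zero so the perfusion chain is an
exact closed loop; curve-level noise robustness is assessed separately on
simulated curve ensembles. One `SeedSequence` per case spawns per-modality
substreams, so cases are bit-reproducible given the seed.

What the phantom does not emulate — realistic anatomy, MR artifacts, PET
sinogram/reconstruction physics, tracer kinetics, registration error —
bounds what passing tests show: they validate the analysis chain
(inversion, fitting, calibration, Boolean metrics), not robustness to
real-image confounds.

## Problem sizes and numerical choices

Default phantom cases hold ~14k brain voxels; randomized fidelity checks
use 100 noise-free and 200 noisy curves, and threshold calibration uses 10⁶
Gaussian voxels — sizes at which every check runs in seconds while keeping
Monte-Carlo error well below the tolerances tested. Geometry equality uses
a 1e-6 mm spacing tolerance; percentile ties follow the `≥` rule; FLAB
iterates to a 1e-6 relative shift in class means (max 100 iterations,
convergence flagged in the result parameters).

## Known limitations

Registration is out of scope (inputs must be co-registered); no leakage
correction, deconvolution CBF/MTT or arterial input functions in the
perfusion chain; FLAB is behaviorally, not bit-level, faithful to the
original software; multi-focal lesions and necrosis sub-segmentation are
not handled; DICOM ingestion is not provided (NIfTI only).
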