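# Methods

`cortbs` simulates and analyzes cortical backscatter (CortBS) measurements of
the tibia: pulse-echo ultrasound of the cortical shell, recovery of the
frequency-dependent attenuation coefficient α(f) and of the cortical
pore-diameter distribution Ct.Po.Dm.D from the subsurface backscatter
coefficient BSC(f), site-matched HR-pQCT-style morphometry, and the
precision and PLS-LOOCV discrimination statistics used to compare imaging
modalities for fragility-fracture discrimination. This note records the
models, the defaults that matter, and the design decisions taken where the
design was genuinely open.

## Pore microstructure model

Pores are straight circular cylinders along the bone long axis (2.5-D
geometry); the morphometric quantity of interest is the cross-sectional
diameter, so tortuosity is ignored. Diameters follow a two-component
lognormal mixture: a Haversian baseline (median 30 μm, log-SD 0.35) and an
optional pathological tail (default median 150–200 μm, weight 0–0.15)
representing merged, unrefilled remodeling cavities; more than half of real
intracortical pores are below 100 μm while pathological pores reach beyond
385 μm, and the mixture reproduces that asymmetry. Cross-section centers
are placed by dart throwing with a hard-core rejection rule (minimum
spacing `max(hard_core, r_i + r_j)`, so the analytic areal porosity
Σπd²/4 / A is additive). Default areal pore density is 15 /mm², a typical
value for human cortical bone; at the default mixture this corresponds to
~1 % areal porosity from the baseline alone.

Acoustic defaults (not reported for the in-vivo system; conventional
cortical-bone values, all configurable): matrix speed 3800 m/s, density
1.9 g/cm³, matrix vBMD 1100 mg HA/cm³; pore fluid 1500 m/s, 1.0 g/cm³.

## RF forward model

The simulated scan mirrors the clinical protocol: a 128-element array,
16-element subaperture swept line by line, three steering angles
(−10°, 0°, 10°), a motorized elevation sweep of ±7° in 1° steps, focus
≈1 mm below the periosteal surface, and a 4–9 MHz analysis band inside a
Gaussian pulse (center 6.5 MHz, 90 % fractional bandwidth, 40 MHz
sampling). Each A-line is synthesized in the frequency domain as

* a specular surface echo with the planar reflection coefficient of the
  soft-tissue/bone interface and a Gaussian specular directivity
  (width 12°), so oblique incidence weakens the reference echo, plus
* an incoherent sum of pore echoes: random phase per (pore, line),
  amplitude ∝ √σ_b(f, d) from the cylindrical-pore kernel, lateral Gaussian
  beam weighting (σ = 0.45 mm), two-way delay, and one-way amplitude decay
  10^(−α(f)·2z/20) with α(f) = α₀ + α_f·f in dB/mm, plus
* white noise at a configured SNR (relative to the RMS subsurface
  backscatter).

One deliberate departure from a frozen 2.5-D geometry: by default each
elevation (sweep-tilt) plane sees an independently re-positioned
cross-section of the same diameter ensemble (`decorrelate_tilts`). Real
pores decorrelate along their axis, and the volumetric sweep is what gives
the physical method its averaging; with literally infinite straight
cylinders the 15 tilt planes would be statistically redundant and no
estimator could reach the accuracy the method demonstrates. The CT forward
model and the inversion kernel keep the strict cylinder geometry.

What the generator does **not** model: soft-tissue aberration, phase
cancellation across the aperture, refraction at the bone surface,
frequency-dependent beam width, anisotropic matrix elasticity, shear-wave
mode conversion. Passing recovery tests therefore demonstrate estimator
correctness under diffuse-speckle conditions, not robustness to those
effects in vivo.

## Spectral processing

Processing follows the CortBS chain: compound envelope images (per-tilt
scan conversion and averaging of the three steered frames), periosteal
surface detection (first envelope maximum above an adaptive threshold
inside the caller's ROI gate, least-squares spline smoothing across lines
and tilts), local beam inclination from the smoothed surface gradient plus
the sweep tilt itself, and the ±10°/±30° acceptance rule for reference and
backscatter use respectively. The quality score is the retained fraction
of candidate scanline-depth cells, gated at 77 %.

The normalized depth-dependent spectrum NDS(z, f) uses Hann-apodized gates
sliding from the surface downward (75 % overlap, half-open [z, z+gate)),
normalized by the inclination-corrected (1/cos², small-angle path
correction) mean surface-reflection spectrum of the reference-accepted
lines: NDS = 10·log₁₀(mean backscatter power / reference power). Gates are
2 mm long by default: 1 mm gates resolve the 1–3 mm fit range more finely
but their ±1 MHz spectral kernel compresses the recovered α(f) slope by
~20 %, which dominates the error budget; 2 mm was chosen as the best
bias/variance compromise and the length stays configurable. Two guards
matter: a 0.4 mm surface guard before the first gate (the Hann tail of the
far stronger specular echo otherwise inflates the shallowest gate,
selectively at low frequencies where backscatter is weakest), and
noise-power subtraction using gates from the echo-free standoff region
(so the noise floor cannot flatten the decay of deep band-edge cells).
Cells with fewer than 4 contributing lines are masked; fewer than 8
reference lines is an error.

### Attenuation

Per frequency, OLS of NDS against depth over 1–3 mm gives the two-way
decay; α(f) = −slope/2 (one-way), and a second OLS of α(f) against f gives
Ct.α₀ (dB/mm) and Ct.α_f (dB/MHz/mm) — the dB convention is 10·log₁₀ of
power ratios throughout, and the one-way report matches the magnitudes of
the clinical parameter ranges. One correction is essential: gated spectral
estimates sample the true spectrum through the window kernel, so the decay
measured at nominal f belongs to the spectral centroid
f_eff = f + σ_w²·d ln S/df (first order), where σ_w² is the main-lobe
variance of the gate window's power kernel (0.30 MHz² for 2 mm Hann gates)
and S the measured mean backscatter spectrum (smoothed quadratically in
dB). With the steeply rising backscatter of micron-scale pores (≈f³) this
compression otherwise biases Ct.α_f low by ~12 % and Ct.α₀ high by ~5 %;
the correction was validated in a deterministic quadrature testbed
(bias after correction < 1 %). It uses measured quantities only.

Accuracy versus precision: over 20 independent phantoms (full sweep
geometry, SNR 30 dB) the median estimate recovers programmed
(α₀, α_f) = (2.0, 0.10) within ~2.5 %. The single-sweep spread is
~7 % for α₀ and ~15 % for α_f — the same order as the clinical short-term
precision of these parameters — and is a speckle information limit set by
band × depth range × independent spatial samples, not an implementation
artifact.

### Backscatter coefficient

Reference-substitution estimate
BSC(f) = C·R²·mean_z[10^(NDS/10)·10^(α(f)·2z/10)] over 1–3 mm; R is the
planar reflection coefficient from configured impedances, C a documented
gate/solid-angle normalization (default 1), and diffraction is assumed to
cancel in the surface normalization. Shape, not absolute scale, feeds the
inversion (which is scale-free); end-to-end the recovered BSC shape matches
the ensemble-theoretical curve within ~4 % RMS.

## Scattering kernel and inversion

The theoretical backscatter kernel is the exact modal (cylindrical-
harmonic) series for a fluid cylinder in a fluid host — continuity of
pressure and normal velocity at the wall, shear in the matrix neglected —
truncated at N = max(10, ⌈ka⌉+4), in the backscatter direction:
differential scattering width (2/πk)|Σ εₙ(−1)ⁿAₙ|². It reproduces the
Rayleigh limit (∝ f³d⁴ for cylinders) to within 0.1 % at ka < 0.1 and is
linear in the size distribution, which the inversion requires. At 4–9 MHz
and d = 30–400 μm, ka spans ~0.1–2.4, covering both Rayleigh and resonance
regimes.

The inversion solves min ‖K(s·p) − BSC‖² + λ‖D₂p‖² with p ≥ 0,
∫p dd = 1 and free scale s, on 64 log-spaced diameter bins over 5–400 μm,
via NNLS on the augmented system. Numerical choices: the second-difference
operator carries zero boundary conditions (density treated as zero outside
the grid) — without them the acoustically near-invisible small-diameter
bins soak up unconstrained mass and the peak collapses to the grid edge;
the data are normalized to unit norm before solving so the smoothing
weight is dimensionless and the solution is exactly scale-equivariant;
λ defaults to the discrepancy principle (largest λ whose relative residual
stays within the noise estimate, scanned on a log grid), with a fixed-λ
mode for reproducibility. Descriptors: Peak = argmax (ties to the smallest
diameter), Q10/Q90 by linear CDF interpolation, FWHM from the outermost
linearly interpolated half-maximum crossings. The density is
number-weighted; a volume-weighted reading of the published distributions
cannot be excluded, so the distribution object keeps the raw density for
re-weighting.

Recovery at the acceptance conditions: Q90 of a lognormal (median 40 μm,
log-SD 0.3) within ~4 % from noiseless BSC and ~4 % median at 5 %
multiplicative noise (20 seeds); a delta at 60 μm returns the peak within
one grid cell.

## Micro-CT synthesis and morphometry

Volumes are annular cortex cross-sections (outer radius 6 mm, thickness
3 mm in the test phantoms) at 60.7 μm isotropic voxels, rasterized with
4× supersampling so voxel values carry correct partial-volume fractions,
then Gaussian-blurred (PSF σ 45 μm) and degraded with additive noise
(25 mg HA/cm³). Pores are mapped from the slab onto the annulus (lateral →
arc length, depth → radial) and replicated along the scan axis. At this
resolution ~30 μm canals are unresolved (partial volume only) while pores
larger than ~90–120 μm segment as voids — the same resolution split the
clinical scanner exhibits.

Morphometry: cortex segmentation thresholds at 50 % of matrix vBMD with
morphological closing and largest-component selection; periosteal/
endosteal contours by per-slice hole filling with the marrow as the
largest hole. Cortical thickness is twice the mean medial-axis
(inscribed-circle) distance per slice. Threshold porosity (Ct.Po_BH) uses
26-connected components of ≥2 voxels below 50 % matrix vBMD inside the
filled cortex; pore density is components per mean cross-section area.
The local porosity map slides a 0.5 mm window over the cortex and applies
the partial-volume calibration Ct.Po_local = 100·(1 − mean vBMD / matrix
vBMD), which attributes the local vBMD deficit to resolved *and*
unresolved pore space; on phantoms with unresolved 30 μm pores its mean
absolute error is ~1.2 %, within the 3.4 % bound such calibrations claim.
Pore diameters default to a partial-volume refinement of the
inscribed-sphere estimate (per-slice vBMD-deficit area of a small shell
around each component, d = 2√(A/π)); pure inscribed-sphere diameters are
available but quantize to the voxel. Distribution statistics use sample
moments with non-excess kurtosis (Gaussian → 3) and linearly interpolated
quantiles.

## Cohort generation and statistics

Synthetic cohorts draw one row per subject from per-group multivariate
normals whose means/SDs default to the published Fx/nFx group values
(anthropometrics, DXA aBMD/T-scores, the eight backscatter parameters, and
seven custom HR-pQCT parameters), with block-diagonal correlation
(0.3 within a modality, 0 across — the real correlation structure is
unreported, so this is an explicit, configurable assumption). BMI is
computed from drawn height and weight; fracture-subtype flags reproduce
the configured vertebral/other/total counts (default 18/21/29 of 55);
~15 % of spine T-scores are set missing and flagged, never imputed.
Because the attenuation effect sizes are large (standardized ≈0.85 per
parameter), the two-parameter attenuation model on these cohorts attains a
median LOOCV AUC of ~0.83 — at the optimistic end of what the clinical
data show, as expected for exactly-Gaussian features with no measurement
degradation.

Statistics: short-term precision is the RMS of within-subject SDs
(absolute) and the RMS coefficient of variation (relative, %). Wilcoxon
rank-sum uses the exact null for ≤10 per group without ties, otherwise the
tie-corrected normal approximation; Spearman ρ is the Pearson correlation
of midranks with a permutation p for n ≤ 9 (exact to n = 7). PLS1 is
NIPALS on autoscaled columns; with full rank it equals OLS, and an
independent implementation cross-checks the coefficients in the tests.
For discrimination (labels ±1), centering uses the midpoint of the class
means ("balanced" centering) so the fitted offset does not depend on the
class composition of a training fold — without this, LOOCV scores pooled
across folds are pessimistic under the null (mean AUC ~0.35 at n = 55);
with it the null mean is ~0.47–0.50, the small residual being the known
small-sample LOOCV effect. Cross-validation is LOOCV or seeded stratified
3-fold; degenerate single-class folds are an error.

SPA variable selection runs Monte-Carlo rounds (random stratified 70 %
subject subsets × random variable subwindows of half the variables, at
least 2 and at most all-but-one) and scores each variable by the mean
out-of-subset error of rounds excluding it minus rounds including it.
Significance is calibrated against a dataset-level label-permutation null
(10 permutations, pooled importances, 95th percentile): a round-level
include/exclude rank test cannot control the across-dataset false-selection
rate, because within one dataset a lucky noise variable is genuinely
helpful and its round-level p-value saturates as rounds accumulate. At the
calibration conditions (n = 50, ten variables, standardized separation 1.5,
300 rounds) power is ~1.0 and the per-variable false-selection rate ~0.04.
The default round count remains 10,000; validation studies use 300 for
runtime, which the calibration shows is already sufficient.

ROC analysis uses the rank (Mann–Whitney) AUC with midrank ties, the
Hanley–McNeil SE (Q1 = A/(2−A), Q2 = 2A²/(1+A)), and a Youden-optimal
operating point (ties resolved toward higher specificity; whether the
published operating points used exactly this rule is unknown, so it is
configurable). Odds ratios are the confusion-matrix cross-product with
Haldane–Anscombe correction and a Woolf log-normal 95 % CI — the published
CIs around the same point estimates are far narrower than Woolf intervals
and their derivation is not stated, so the point OR is the tested
quantity. Two AUCs are compared with the Hanley–McNeil z-test with a
configurable correlation.

Missing spine T-scores are handled by listwise deletion per endpoint,
consistent with the varying per-model n of the published models.

## Validation studies and problem sizes

`cortbs.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) runs: the integer reconstruction of the three
internally consistent published vertebral confusion matrices; the binormal
AUC implied by the attenuation-intercept group statistics; attenuation
recovery (20 phantoms, full sweep geometry); Q90 recovery (20 noisy BSC
realizations); the Rayleigh-limit slopes; morphometry accuracy on an 8-slice
annulus; null LOOCV calibration (50 cohorts) and SPA calibration (20 + 20
designs, 300 rounds); and the attenuation-model discrimination AUC on 50
effect-programmed cohorts. Problem sizes were chosen so the whole set runs
in roughly a quarter hour on one CPU.

## Known limitations

* The backscatter model is single-scattering and fluid–fluid; shear-wave
  conversion and multiple scattering at high porosity are outside the
  model, and absolute porosity is not estimated from ultrasound.
* The inversion's small-diameter bins (< ~15 μm) are acoustically nearly
  invisible in the 4–9 MHz band; their mass is controlled by the
  regularization prior, not the data.
* Cohort variables are exactly Gaussian with an assumed block correlation;
  discrimination results on them bound the idealized, not the clinical,
  performance.
* Single-sweep attenuation precision (~7–15 %) is an information limit of
  the measurement configuration; applications needing tighter values must
  average repeated sweeps.
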