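# Methods

This note documents the models, numerical choices and limitations of
`dmsapk`, in the order data flows through the pipeline.

## System model (projector)

The SPECT operator is a rotation-based projector. For each view the volume
is rotated into the detector frame (detector on the +y side, view 0
anterior, counterclockwise angles), each constant-depth plane is blurred
with the distance-dependent collimator-detector response
σ(d) = √(σ₀² + (s·d)²), multiplied by the attenuation factor
exp(−∫μ dl) accumulated voxel-by-voxel toward the detector with a
half-voxel offset (the emitting voxel contributes half its own μ·Δx), and
summed along the detector normal. The detector grid equals the in-plane
volume grid.

The in-plane rotation is bilinear interpolation materialised as a sparse
matrix per angle, so the backprojector is the exact matrix transpose and
the adjoint identity ⟨Px, y⟩ = ⟨x, Pᵀy⟩ holds to machine precision — the
property the multiplicative OS-EM updates rely on. The Gaussian plane blur
(symmetric kernel, zero-padded) is self-adjoint. Interpolation makes count
conservation exact only at cardinal angles; at intermediate angles per-view
totals deviate by ≲0.2% at 64³ and ≲0.5% at 32³, which the tests treat as
the projector's stated accuracy.

Defaults: σ₀ = 0.2 cm, slope = 0.02 (representative of a low-energy
ultra-high-resolution parallel-hole collimator), soft-tissue μ = 0.15 cm⁻¹
at 140 keV, physical half-life exactly 6.0 h. All are configurable.

## Synthetic phantom and acquisition

The phantom is two ellipsoidal kidneys (semi-axes 1.5 × 1.5 × 3 cm — an
adult 3 × 3 × 6 cm organ scaled by a pediatric factor of ½ — centred
±6 cm laterally, 2 cm posterior) inside an ellipsoidal soft-tissue body
(semi-axes 12 × 8 × 12 cm) on a 64³ grid of 0.4375 cm voxels. A chosen
fraction (default 0.3) of the injected activity (default 74 MBq) is uniform
over the kidney voxels; the remainder is uniform body background, standing
in for liver/spleen and soft-tissue uptake at background level. Attenuation
is uniform soft tissue inside the body — deliberately matching the
binary-fill attenuation model the quantification chain assumes.

Acquisition: 120 views over 360° by default (60 in the scaled-down test
configuration), 8 s per view, sensitivity 5000 CPM/MBq, photopeak
140 keV ± 7.5%, scatter window 108–129 keV. Expected photopeak counts are
sensitivity × duration × projected decayed activity; Poisson noise is drawn
from a single seed. At these settings a study collects ~1–2 M counts,
a realistic clinical count level. The scatter model is phenomenological: a
3 cm-blurred copy of the primary counts, scaled 0.5 into the scatter window
and (optionally, default 0) by a photopeak scatter fraction into the
photopeak, whose noise-free expectation is stored as the "matched" scatter
estimate. It exercises the body-contour and compensation machinery but is
not photon transport: no energy spectra, septal penetration or detector
resolution, so passing tests certify the algorithms, not scatter physics.

## Quantification chain

OS-EM uses deterministic angularly-strided subsets (`views[i::n_subsets]`),
sizes balanced to within one view when the view count is not a multiple of
the subset count (e.g. 120/16). The initial image is a data-scaled constant
on the sensitivity-image support, which makes the reconstruction exactly
scale-equivariant at any iteration count. Zero-sensitivity voxels are
masked from the update; the scatter estimate enters the denominator's
forward projection. Defaults: 5 iterations × 16 subsets.

Without CT, the attenuation map is derived from the scatter window:
reconstruct the scatter-window counts (2 iterations × 10 subsets, no CDR)
with a uniform initial μ map filling the camera-orbit envelope, average
axially over the kidney slice range, threshold at 0.20 of the collapsed
maximum, fill holes, keep the largest component, fill with μ_soft and
replicate axially. On the noiseless synthetic body the 0.20 threshold
recovers the cross-sectional area to within ~1% at 64³ (the check that
motivated the default; the clinical procedure is calibrated the same way,
by judging contours against the visible body outline).

The kidney VOI is threshold-based: voxels ≥ 0.40 of the image maximum, two
largest connected components, summed. Two refinements are on by default
and documented here because the plain version is measurably biased: the
threshold is evaluated on a 1-voxel-smoothed copy (a raw noisy maximum
inflates the cut and shrank the VOI by ~30% in tests), and the VOI is
dilated by one voxel to recapture partial-volume tails that the finite
reconstruction resolution pushes outside the sharp contour (the plain VOI
loses ~13% of kidney activity even noise-free). With both, end-to-end
recovery with the true attenuation map is within ~2–3% (≤5% bound), and
with the scatter-window map within ~4–8% (≤15% bound). Both can be set to
zero for the plain behaviour.

Sensitivity calibration follows the thin-flask convention: counts / minute
/ (fill activity decay-corrected to the acquisition), in CPM/MBq. Measured
fractions of injected activity are decay-corrected to injection time by
default so fitted parameters are biological.

## Planar and hybrid quantification

Planar kidney counts are corrected per view (dual-window scatter
subtraction with k = 0.5 — an assumption, the clinical method being
unstated; background mean per pixel from a disjoint ROI), combined across
anterior/posterior by the conjugate-view geometric mean, and
attenuation-corrected by exp(μL/2) with L the body thickness *at the
kidneys' lateral position* (using the global anteroposterior thickness of
an elliptical body overestimates attenuation by ~15–20%). The geometric
mean makes the correction independent of kidney depth, which is what lets
one SPECT-anchored factor (MBq per corrected cps at the clinical time)
transfer to the second planar time point; in simulation the transferred
activity lands within 10% of the decayed truth.

## Biokinetic fitting and TIAC

Cohort records are binned into 10-minute bins aligned at t = 0 (bin time =
true midpoint; SD/CV reported only for n ≥ 2). The fit is weighted
nonlinear least squares of F_S(a₂ − exp(−ln2·t/T₁)) with bounds
F_S ∈ (0, 1], T₁ > 0 and a₂ ≥ 1 — the last enforces a non-negative modelled
fraction at t = 0 given a₁ = −1. Initialisation is data-driven (plateau
estimate / 1.2, T₁ = 1 h). SEs are asymptotic WLS (inverse weighted normal
equations scaled by residual variance); TIAC uncertainty is Monte-Carlo
propagation through the closed form with bound truncation, deterministic
given its seed.

Weighting is a genuine open choice: the per-bin patient count n seems
natural, but on the shipped binned table it lets the heavily populated
2.7–3.2 h clinical cluster dominate and drags T₁ to ~2.3 h with an
essentially flat uptake phase. Equal per-bin weighting reproduces the
published parameters within their standard errors (F_S 0.304 ± 0.070,
T₁ 0.80 ± 0.40 h, a₂ 1.20 ± 0.31; TIAC 2.86 ± 0.28 h) and is therefore the
default; `"n"` and inverse-variance weighting remain available options.

The TIAC closed form treats T = ∞ as rate 0 exactly (no "large number"
surrogate) and is property-tested against adaptive quadrature of the
decay-weighted curve. The comparison table reports each model's closed-form
TIAC and its whole-percent difference from the reference; for the Evans
parameter set the closed form gives 1.37 h, which does not reproduce that
study's printed 3 ± 3 h — the table reports the computed value rather than
asserting the printed one.

## Cohort generator and regression

Synthetic cohorts default to the study conditions: 77 patients
(17 male / 60 female; 54 retrospective with one clinical SPECT point, 13
early-arm and 10 delayed-arm with one extra planar point), clinical times
uniform on 1.9–3.75 h (the inter-patient distribution of clinical times is
not known beyond its range; uniform is a flagged assumption), early
0.25–1.5 h, delayed 4–6 h. Ages are lognormal with median 4 y (σ_log = 0.7,
clipped to 4 months–16 y); weight follows the coarse pediatric growth rule
2·age + 8 kg with 12% lognormal spread. Between-patient variability is a
lognormal multiplier on F_S with CV 0.25 (the 20–30% spread seen in uptake
at the clinical time); female patients get an additive +0.064 on the
plateau F_S·a₂; measurement noise is multiplicative Gaussian, default
CV 0.10 (typical quantification uncertainty), truncated to [0, 1].

Median regression minimises Σ|y − Xβ| as a linear program (HiGHS), which
is exact — zero-residual designs are recovered to machine precision and
small problems match a brute-force subset-enumeration oracle; statsmodels'
QuantReg serves as an independent cross-check in tests, never as the
implementation. CIs and P values use a nonparametric patient-resampling
bootstrap (2000 resamples by default; percentile CIs, normal-approximation
P from the bootstrap SE) with a fixed seed, a documented substitution for
the unspecified analytic variance estimator of the original commercial
software. The analysis layout mirrors the published one: univariate fits
for age (per year), age category (0–<3 reference), weight (per 5 kg) and
sex; multivariable age + weight + sex.

## Problem sizes and determinism

Reconstruction tests and the acceptance script run a 64³ phantom with 60
views (examples and unit tests use 32³/24 views), 10 noise seeds for the
quantification-error average, 100 replicates for parameter-recovery and
CI-coverage checks with 250–300 bootstrap resamples — sizes chosen to keep
the whole suite in a few CPU-minutes while leaving the Monte-Carlo
assertions comfortably away from their thresholds. Every stochastic stage
takes an explicit seed and is bit-reproducible; configuration files reject
unknown keys and artifact tables carry a hash of the fully resolved
configuration.

## Known limitations

Analytic projector, not Monte Carlo: no septal penetration, energy
resolution, or depth-dependent scatter physics. Uniform-body attenuation
only (the quantification chain assumes exactly the model the phantom
implements, so attenuation-model mismatch is not measured). Single
anthropometric phantom, no age-specific phantom family, no renal
focal-defect modelling, no liver/spleen kinetics, and no absorbed-dose
(S-value) computation — the TIAC is where this package stops.
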