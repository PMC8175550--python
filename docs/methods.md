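# Methods

This note records the models implemented in `zfo`, their assumptions, the
defaults that matter, and the choices made where the underlying measurement
protocols leave the implementation open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## OCT biometry

OCT reports optical path length, the product of geometric distance and the
tissue's refractive index. The module converts boundary gaps to physical
thickness by `d = Δpx · pixel_depth / n` with scalar indices cornea 1.33,
anterior/vitreous chamber 1.34, lens 1.40 and neural retina 1.38; the lens
value is the single equivalent index of the gradient-index spherical fish
lens, and the group-index/phase-index distinction is deliberately ignored —
the protocol works with single scalars per tissue. The default axial pixel
depth is 2 µm. Axial length is anatomically defined from the apical corneal
epithelium to the anterior border of the RPE and is computed as the sum of
the five compartments, which makes it exact under the boundary convention
that a boundary pixel belongs to the posterior compartment (half-open
intervals).

Boundary segmentation supports two paths. The manual path wraps
operator-marked boundaries unchanged, preserving fidelity to protocols in
which borders are marked by hand. The automated path smooths the averaged
A-scan (Gaussian, σ = 1 px), differentiates it, and refines each of the
first five boundaries to the strongest signed step within ±10 px of a
supplied prior layout; optional step polarities disambiguate closely spaced
boundaries (the anterior chamber of an adult zebrafish is only ~5 µm,
about 3 px of optical path). The sixth boundary is always the rising edge
of the brightest band — the sharp anterior border of the melanin-rich RPE —
located as the largest intensity step between the vitreous/retina boundary
and the band peak, which is robust to speckle shifting the peak position
within the band. Without a prior, the six most prominent steps anterior to
the band peak are used; the band's posterior falling edge is explicitly
excluded from candidacy. Whether axial length is taken from the averaged
A-scan (default) or a single central column is configurable; averaging was
chosen as the default because the phantoms are laterally homogeneous and
averaging is the better-conditioned estimator.

## Eccentric photorefraction

The defocus of the eye maps onto a linear brightness gradient across the
pupil; the slope of an ordinary least-squares line through the profile,
multiplied by a device conversion factor, gives the refractive error in
diopters. Calibration regresses lens power on mean measured slope — that
direction makes the regression slope directly the factor that converts
slope units into diopters. Replicate slopes are averaged before conversion.
Relative refractive error subtracts the wild-type group mean, cancelling
the shared small-eye retinoscopic offset (light returning from the
nerve-fiber layer instead of the photoreceptors inflates absolute hyperopia
in small eyes); no explicit artifact-correction model is implemented.

Profile phenotyping operates on the normalized profile (positions mapped to
[0, 1], brightness min-max scaled), so its thresholds are unit-free and the
classification is invariant to affine brightness transforms. A global line
and the best two-segment piecewise line (breakpoint scanned over interior
samples, ≥3 samples per segment) are fitted. *Bifocal*: segment slopes of
opposite sign, both at least the slope threshold, and the split removes
≥50% of the global residual sum of squares. *Absent*: no reliable gradient,
meaning |global slope| < 0.05 per pupil width **or** fit R² < 0.2 — the R²
condition is needed because min-max normalized pure noise always spans the
unit range, so slope magnitude alone cannot separate noise from gradient.
Otherwise *monofocal*. All three thresholds are configurable; the defaults
are design choices, as the visual criteria they operationalize are
qualitative. Pupil-image handling is limited to CSV profiles; extracting
profiles from raw camera frames is out of scope because eccentricity and
working distance of a given rig determine the meridian geometry.

## Lens opacity and cataract

The opacity ratio binarizes the lens by Otsu's between-class-variance
threshold computed from intensities inside the lens mask only — the de
facto standard automated threshold for bimodal binarization. Otsu always
produces a split, so a guard is applied: if the upper class exceeds the
lower by less than 10% relative contrast the lens is treated as uniformly
transparent (ratio 0, `degenerate` flag), preventing a noise-only lens from
being split in half.

The cataract call mirrors the visual "nuclear ring clearly visible"
criterion with one interpretable number. The image is first mapped to
lens-over-background contrast units, `(I − mean_outside)/(mean_inside −
mean_outside)`, making the score exactly affine-invariant; the radial mean
profile about the lens centroid is compared with a wide (21-bin) median
baseline, and the ring score is the maximal elevation over radius fractions
0.1–0.8. The default call threshold is 0.10 contrast units; there is no
protocol-stated value, so it is exposed as a parameter. Radial profiles
were preferred over 2-D template matching because the phenotype is, by
definition, concentric.

Prevalence is rounded half-up to an integer percent. Group contrasts in
prevalence are reported as percentage-point differences by default
(consistent with reading differences off prevalence bar charts); a
relative-increase mode is available.

## Optokinetic response

The sawtooth generator and the detector form a matched pair. Slow-phase
velocity is `gain × drum velocity` in the stimulus direction (positive
angle = nasal); resets of fixed amplitude occur at a fixed rate, falling
exactly between two frames so every slow segment is exactly linear.
Detection computes central-difference velocity and marks samples as fast
phase when speed exceeds 3× the drum speed *and* the sign opposes the
slow-phase direction; remaining runs of ≥3 frames are slow phases with
least-squares velocities. The 3× factor is a detector design choice
validated against generator ground truth; it is configurable. Central
differences contaminate exactly the two samples flanking a reset, and both
are excluded by the criterion, which is what makes unit gain on a noiseless
perfect-tracking trace exact rather than approximate.

Gain uses the median over slow-phase velocities (robust to residual
saccade contamination at segment edges); the mean is available. "Three or
more consecutive nystagmus patterns" is operationalized as ≥3 consecutive
(slow, fast) cycles with no gap exceeding 1 s, and a staircase response is
positive only when both stimulus directions meet that rule. The acuity
threshold is the highest frequency with a positive response on the
ascending grid (0.15 cpd start, 0.05 cpd steps), the terminating frequency
appearing twice for verification; a negative response at the lowest
frequency is flagged as below-grid rather than assigned a number.

## ERG

The biphasic response template is a difference of two gamma kernels
(`(t/tp)^2 exp(2(1−t/tp))`, unit peak) with default peak times 30 ms
(negative A lobe) and 120 ms (positive B lobe) — plausible teleost b-wave
timing; the protocol defines only the extraction rules, not a waveform. The
positive-lobe coefficient is solved numerically (Brent) so the noiseless
template maximum equals the designed B-wave amplitude exactly, which gives
the recovery tests a closed-form oracle. Baseline correction subtracts the
mean over the 50 ms immediately before the *first* stimulus (computing it
once, not per stimulus, is the default; per-stimulus correction of a
drift-free recording would be identical). Epochs aligned at the onsets are
averaged point-wise with length min(configured 1000 ms, inter-stimulus
interval, data remaining after the last onset). The B-wave amplitude is
the maximum of the averaged corrected epoch within 0–500 ms post onset
(configurable); the analog acquisition band-pass is treated as an
instrument property and no digital filter is applied by default. A-wave
metrics are not extracted.

## Cohort statistics

Paired eyes violate independence, so the model of record is the
random-intercept linear mixed model `y_ij = β0 + β1·I(mutant) + u_i +
ε_ij` fitted by REML (statsmodels `MixedLM`), genotype fixed, fish random,
eyes exchangeable (no eye-side fixed effect). REML was chosen over ML as
the standard small-sample estimator for variance components. β1 is
reported with its Wald standard error and normal-reference p-value. A
cohort whose residual variance is numerically zero (noiseless simulations)
is degenerate for REML; the fit then falls back to the exact group-mean
difference with `converged=False`, which is also the correct GLS answer
for a balanced design. Size matching keeps wild-type fish whose body
length is within 10% of the mean mutant body length, filtering whole fish
(both eyes together). Ages are analyzed strictly cross-sectionally; no
longitudinal model is offered because fish are not individually labelled
across time points. Welch's ANOVA (pingouin) serves the heteroscedastic
multi-group outcomes; its two-group case equals Welch's t², which the test
suite uses as an independent oracle alongside a hand computation of the
Welch–Satterthwaite formula. No multiple-testing correction is applied
across outcomes or ages by default.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* the analyses rely on: optical-path
geometry and a hyperreflective RPE band (OCT), slope-encoded defocus
(photorefraction), sawtooth kinematics (OKR), biphasic post-stimulus
deflections with a quiet pre-stimulus baseline (ERG), concentric nuclear
rings (lens), and additive random-intercept variance components (cohorts).
Noise models are the simplest matching each instrument class:
multiplicative Gaussian speckle for OCT, additive Gaussian elsewhere. The
default cohort design is 20 fish per group, two eyes per fish, a −47 µm
genotype effect on a 1000 µm-scale outcome, 15 µm between-fish SD and
10 µm residual SD — between-fish variation on the order of 1.5% of the
mean and within-fish measurement error somewhat smaller, a realistic
ratio for ocular biometry at this scale. The phantom cohorts used for the
percent-change recovery are 24 eyes per group at a 1000 µm wild-type
axial length (the adult wild-type compartment proportions rescaled), the
mutant group uniformly scaled by 1.07, with 5% speckle; group size and
speckle level follow the corresponding 6-month study design.

Not emulated: physically based speckle statistics, refraction at curved
interfaces, eye-movement biomechanics (saccades are instantaneous),
oscillatory potentials or photoreceptor nonlinearities in the ERG, and
histological texture inside lens rings. Consequently, passing recovery
tests demonstrates correctness of the estimators under the stated models —
boundary quantization, threshold behavior, variance-component recovery —
not robustness to arbitrary real-world artifacts.

All generators are pure functions of their spec, including the seed;
designed quantities are carried in returned ground truth and never
re-derived from rendered pixels, so test oracles remain independent of the
analysis paths they check. Ring-based ground truth reports the *rendered*
mask fraction, not the analytic target, keeping oracles exact under pixel
quantization.

## Problem sizes

The shipped experiments are sized for a desk machine: 200 replicate
cohorts of 80 rows for the mixed-model recovery, 24–40 lens images of
128×128 px per prevalence design, 48 phantoms of ~770×32 px for the
percent-change recovery, 30 s traces at 96 frames/s. The full acceptance
run completes in well under a minute on one CPU.
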