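# Methods

This note documents the models, conventions and numerical choices behind
`gaitscreen`, and what the synthetic-data tests do and do not establish
about real recordings.

## Angle and Fourier conventions

Joint angles are signed: a straight joint (distal segment continuing the
proximal one) is zero, counter-clockwise is positive, range (-pi, pi].
The image y axis is flipped on read so this convention holds in a
right-handed frame. Profiles are unwrapped before resampling and linearly
interpolated onto a uniform 100-point cycle grid; at 50 Hz and walking
stride durations the linear-interpolation error is a few milliradians
(it shrinks quadratically with sampling density), which is negligible
against digitization noise.

A cyclic profile is represented by one-sided complex harmonics
`x(t) = c_0 + sum_n 2 Re(c_n e^{i 2 pi n t})`, n = 1..8. Eight harmonics
reproduce smooth joint-angle profiles essentially exactly; the
band-limited round trip and the Parseval identity
`var(x) = 2 sum |c_n|^2` hold to 1e-10 and are asserted in tests, so no
truncation loss is hidden in the transform itself.

**Affine components.** Mean = `c_0`; amplitude = `sqrt(sum |c_n|^2)` (the
harmonic energy norm — for a single harmonic of peak amplitude `b` it
equals `b/2`; this is the eROM measure, smooth and monotone in
oscillation size); phase = `-arg(c_1)/2pi` of the total forelimb angle,
as a cycle fraction. Phase alignment rotates *all* joints of a stride by
the single reference phase (a whole-stride time shift), so within-stride
joint timing — coordination — is untouched. Per-joint alignment exists
only inside `phase_preserving_average`, for presentation averages of
joints whose phase varies relative to the reference.

**Coordination.** After mean removal, per-joint amplitude normalization
and reference-phase rotation, the remaining coefficients of the six
analysis joints are flattened to 96 real variables. The vector is
invariant (1e-8) under per-joint offset and scale and global time shift —
the defining contract, tested by construction. Amplitude normalization
before the coordination PCA is a deliberate choice: amplitude is already
carried by the dynamic-posture block, and normalizing prevents eROM from
leaking into the coordination components. Joints with amplitude below
1e-6 rad have no defined phase/shape and contribute zeros.

The 96 variables are redundant (normalization and phase-zeroing consume
degrees of freedom), but the full count is retained and reduced by PCA;
only the first 12 coordination components enter the model. PCA is
centered, unstandardized (inputs are dimensionless and commensurate),
with a deterministic sign convention (largest-magnitude loading entry
positive).

## Gait variables and dimensionless scaling

Duty factors use a kinematic contact proxy: a hoof is in stance while its
horizontal speed stays below 10% of the stride-mean withers speed for at
least 3 frames; touchdown is the first stance frame. On the synthetic
walker (which has exact stance built in) detection is within one frame of
truth. Clearance is `1 - min/max` of the trunk-to-hoof distance
(withers->forehoof, hip->hindhoof; the forelimb has no "hip" landmark,
so the withers is its fixed trunk point). Hindlimb phase is the
fore-to-hind touchdown lag as a cycle fraction. Dimensionless conversion
follows dynamic-similarity scaling with the cumulated
snout-eye-ear-withers-croup-tailbase chain length as reference length
`h`: `d/h`, `f sqrt(h/g)`, `v/sqrt(g h)`, so `v = d f` is preserved.

Plausibility filtering keeps strides whose gait variables lie inside
configurable closed intervals (defaults: duty factors and phases in
[0, 1], dimensionless speed in [0, 3], frequency 0.1-10 Hz) and whose
Procrustes start-end disparity is at most 0.02 — noiseless cyclic strides
score below 1e-12, so the threshold is pure digitization-noise headroom.

## The subject model

For an outcome theta in {mass, size, age}, one stride contributes one row
of 34 predictors: sex (male = 1), 9 gait variables, 12 dynamic-posture
values, 12 coordination components. Predictors are centered and scaled by
the training set; theta is log-transformed for mass (strictly positive,
right-skewed), identity for age and size (size scores can be negative),
then standardized. On that scale the priors are Normal(0, 2) for
intercept and slopes (the two-standard-deviations-of-observed-values
width), Half-Cauchy(1) for the residual scale eps, and Gamma(2, 0.1)
(mean 20) for the Student-t degrees of freedom nu — weakly informative:
the likelihood is near-normal unless the data demand heavy tails. The
model has 36 free parameters (intercept + 34 slopes + eps); nu is an
auxiliary shape parameter of the observation model.

**Sampling.** The Student-t likelihood is augmented as a scale mixture:
`e_i | lam_i ~ N(0, sigma^2/lam_i)`, `lam_i ~ Gamma(nu/2, nu/2)`. A Gibbs
sweep draws the 35 regression coefficients exactly from their conjugate
multivariate-normal conditional (Cholesky solve), slice-samples log sigma
and log nu against the *lam-marginalized* Student-t likelihood (collapsing
the weights removes a slow coupling that otherwise throttles nu mixing),
and redraws lam from its Gamma conditional. Chains are fully independent
and deterministic given the seed. Desk defaults (4 chains, 500 warm-up +
1000 kept sweeps) give split R-hat <= 1.01 and ESS > 2000 for every
parameter in about two seconds per fit; a `profile="reference"` option runs
32 chains of 2^14 + 2^14 sweeps. Ensemble samplers were rejected after
direct measurement: at 39 dimensions their finite-ensemble bias
under-disperses the posterior by ~15%, which silently destroys interval
coverage.

**Prediction.** Per stride, theta is drawn from the Student-t observation
model at the stride's predictor values across a seeded subsample of the
flattened posterior (default up to 4000 draws), inverse-transformed, and
summarized as Delta = predicted - actual. Calibration is verified on
cohorts whose outcome is generated from the model itself with known
coefficients: 95% credible intervals cover the generating slopes at
~95% (>= 90% asserted over 20 replicates) and pooled in-sample mean Delta
stays within 0.1 sd of zero.

## Screening and the shrinkage caveat

A subject is flagged for consistent underestimation when > 75% of its
pooled predictive samples fall below the actual value *and* more than
half of its strides have negative mean Delta. Verdicts are
order-invariant and recomputable by brute force from stored samples.

One property of norm-referenced inference deserves emphasis: because the
kinematic age signal is noisy (predictive sd ~ 2 h by design), the
posterior mean age shrinks toward the training-set mean. Subjects far
*above* the mean age are therefore mildly underestimated even when
perfectly normal, and subjects far below it overestimated. The screen is
accordingly applied the way a screening study uses it — per-subject
verdicts on the out-of-sample (LBW) individuals, against the pooled NBW
calibration — not as a per-subject test of the reference population
itself. In the synthetic cohorts the delayed subgroup (5 h injected
delay) is flagged with ~100% sensitivity while young, non-delayed LBW
subjects show the mirror-image overestimation and are never flagged;
both behaviors match the structure of the real study's per-animal report.

## The synthetic cohort

The generator emulates the study conditions: 58 subjects in litters of
12, 4-8 strides each, ages uniform in 1-10 h, sex balanced. Birth weights
are a two-component mixture (normal bulk 1500 +- 250 g plus a 12%
growth-restricted component at 720 +- 90 g); the LBW rule — lowest litter
decile AND <= 800 g — then yields the ~10% LBW share of the study.
Features are linear in (effective age, mass, size, sex) plus independent
Gaussian noise; slopes come from an information budget: for each driver,
the summed squared signal-to-noise over its carrier features equals
`1/sd_target^2 - 1/prior_var`, with targets sd(age|kinematics) = 2 h
(the scale on which the 75% rule is meaningfully exercised, matching the
predictive-sd scale of the study's report), 0.15 kg for mass and 0.5
units for size. Coordination lives in a 20-dimensional latent space
embedded orthogonally in the 96 variables; the first 12 latent dimensions
have unit variance and carry all the signal, so the 12-component PCA
retains it. The injected delay (5 h) applies to LBW subjects recorded
above 5 h of age, and drives their kinematics via effective age =
age - delay.

Per-stride harmonic representations are synthesized from each row's
posture and coordination (base joint shapes plus latent-driven
perturbations, eROM-scaled, phase-jittered), so the stored features and
profiles are mutually consistent and the Fourier stage can be tested
end-to-end.

**Walker.** Landmark fixtures come from a planar 17-landmark linkage:
constant-speed trunk, hooves following prescribed cyclic trajectories
with exact stance, limb joints solved by closed-form two-link inverse
kinematics with a prescribed distal flexion wave. Periods are an integer
number of frames, so strides are exactly periodic (Procrustes
cyclicality ~ 1e-31) and touchdown frames are known exactly. The walker
exercises the front half of the pipeline (I/O, segmentation, kinematics);
its gait does not vary with the cohort's feature table, which exercises
the back half — the two meet at the feature-row contract.

**What passing tests do not show.** The generator is linear, Gaussian and
stationary; real piglet kinematics have outliers (the reason for the
Student-t likelihood), non-linear maturation, within-subject correlation
and digitization failures that only the episode/stride filters address.
Synthetic results validate the machinery and its calibration, not the
biological effect sizes.

## Problem sizes and runtime

Desk-scale defaults throughout: cohorts of ~350 strides, 4 x (500 + 1000)
Gibbs sweeps per fit, 20 replicate cohorts for the coverage check, 3 for
the screening check; the full test suite runs in about a minute and the
acceptance script in under one minute on a single CPU. The heavy reference
sampler profile (32 x 2^14) is available behind a flag for reference
runs.
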