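# Methods

## Signal model and fitting

The forward model is the ideally spoiled steady-state gradient-echo
equation S(α) = M0 sin α (1−E1)/(1−cos α E1), E1 = exp(−TR/T1), with
mono-exponential echo decay exp(−TE/T2*). Assumptions: perfect spoiling,
instantaneous excitation, no magnetization transfer, no slice-profile
effects, and a purely real T2* decay common to all echoes of a flip angle.
Angles are degrees at every interface and converted to radians exactly
once; times are ms everywhere (files and APIs alike) to avoid silent unit
drift.

T1 fitting uses the two-point linearized solve (y = E1 x + b with
y = S/sin α′, x = S/tan α′, α′ = κα). With exactly two flip angles per
protocol an iterative least-squares adds nothing; an n-point regression
variant exists for protocols with more angles. The solve is invariant to
any common multiplicative factor on the two signals, which is what makes
echo-averaged multi-echo data fit correctly: a spatially varying T2*
attenuates both flip-angle averages by the same voxel-wise factor, which
is absorbed into M0. Fits with E1 outside (0, 1) or T1 outside the
plausibility bounds (default 1–10 000 ms) are flagged invalid, never
clipped, so QC masks stay honest; degenerate voxels (zero signals, zero
denominator) produce invalid flags rather than exceptions.

## B1 correction

The double-angle method inverts cos(κα) = S(2α)/(2 S(α)) on a long-TR FSE
pair at nominal 60°/120°. The scanner-specific calibration factor applied
to κ is exposed as `scale_const` (default 1.0; the value used on any
particular scanner is a site calibration, not derivable here). Validity
is withdrawn where the arccos argument leaves [−1, 1], the low-angle
signal is non-positive or below a floor, or κ leaves plausible transmit
bounds (default [0.25, 2]).

Because the true transmit field varies on centimeter scales, the map can
be smoothed before use (default FWHM 8 mm when smoothing is requested;
the pipeline default is no smoothing since simulated B1 and qT1 share a
grid). Smoothing is masked normalized convolution — Gaussian-smooth
κ·mask and mask separately and divide — which preserves constant fields
exactly and fills isolated invalid voxels from their neighbourhood
instead of dragging the brain edge toward zero. Resampling to a qT1 grid
is trilinear through the NIfTI affines (RAS, 0-based voxel indices), with
nearest-neighbour transfer of the validity mask. Where the B1 map is
invalid the fit falls back to κ = 1 and the voxel is excluded from the
validity mask.

## Protocols

Two qT1 protocols are built in: single-echo (α = 3°/14°, TE = 4.948 ms)
and multi-echo (α = 3°/24°, TR = 28.5 ms, TE = 3.36, 7.78, 12.20, 16.62,
21.04 ms). The single-echo TR is not pinned down by the protocol
description this mirrors; it is a configuration value defaulting to
7.0 ms (a typical 3T SPGR repetition time), and simulation and fitting
always read the same declared value. Multi-echo data are collapsed to one
volume per flip angle before fitting by an unweighted arithmetic mean
over echoes; TE-weighted and first-k-echo alternatives are provided for
exploring the precision/accuracy trade-off of late echoes. Spatial
alignment between protocols is an injected transform hook that defaults
to identity on synthetic data; real registration is out of scope.

## Phantom and cohort generator

The phantom is an ellipsoidal shell (a crude cortex) parcellated into
azimuthal sectors split at the mid-sagittal plane into hemispheres; with
34 sectors per hemisphere the parcels take Desikan-Killiany names.
Default tissue values are representative 3T cortex: T1 = 1400 ms,
T2* = 50 ms, M0 = 1. The default transmit field is a second-order
polynomial bowl peaking mid-volume over [0.85, 1.15]; smoothed-random and
uniform fields are options. Noise is Rician on magnitude images (the
magnitude of a complex Gaussian perturbation), with a Gaussian option for
debugging; all randomness is seeded and identical seeds give bit-identical
volumes.

Cohorts mirror the modeled study's shape: 14 patients / 7 controls,
patient ages 47 ± 14 vs control 28 ± 9.3 years (truncated normals —
truncation by rejection, not clipping, to avoid boundary point masses),
57% male in both groups, chlorpromazine-equivalent dose 548 ± 320 mg in
patients only. Regional true T1 is baseline + group + sex + age·slope +
dose·slope + a per-subject, per-ROI Gaussian deviation. Defaults: +80 ms
patient elevation in the 13 reference parcels (all parcels for non-DK
catalogs), −50 ms for females, −0.5 ms/year, −0.05 ms/mg, and a 50 ms
between-subject SD chosen as literature-typical inter-subject variability
of cortical T1 at 3T (≈3–5% of the mean). What the generator does not
emulate: real anatomy and gyrification, partial-volume mixing, k-space
artifacts, motion, and registration error — so green tests demonstrate
the correctness of the estimators under the stated model, not robustness
to those real-data effects.

## Statistics

Group inference is per-ROI OLS of mean regional qT1 on a patient
indicator, age, and sex (female = 1, so negative sex coefficients read
"females lower"), two-sided t-tests on n − 4 df. Cohen's d is derived
from the group t-statistic as d = t√(1/n₁ + 1/n₂) with
SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))); this conversion reproduces
every printed reference-table effect size from the printed differences
and SEs, which is why it is the one implemented. Raw (unadjusted) group
differences are reported alongside the adjusted coefficient since either
could be the quantity printed in a summary table. The covariate analysis
is restricted to patients and fits age, sex, and dose jointly, so each
coefficient is tested while accounting for the other two. FDR families
are per hemisphere, per analysis, per protocol (Benjamini-Hochberg via
statsmodels); adjusted p-values never fall below raw ones, and
thresholding them at α reproduces the step-up rejection set exactly.
Rank-deficient designs (e.g. a single-sex sample) raise an error naming
the collinear column rather than silently dropping it.

## Protocol noise comparison

The multi-echo vs single-echo precision question is settled by Monte
Carlo under a matched total signal budget: each protocol's M0 is scaled so
the summed noiseless signal over all of its acquired volumes is equal,
and the same per-image Rician σ is applied. This matching expresses
"equal signal delivered per scan": the multi-echo protocol spreads its
budget over ten readouts (2 flip angles × 5 echoes) whose later echoes
are attenuated by T2* decay before averaging, while the single-echo
protocol concentrates it in two readouts. Under this convention the
multi-echo fit's ROI-mean SD is roughly twice the single-echo SD at
T2* = 50 ms, stably across replicates. The direction is
convention-dependent — at identical M0 and σ the larger flip-angle
signals of the 28.5 ms-TR multi-echo protocol win instead — so the
matching rule is stated explicitly rather than left implicit.

## Validation experiments and sizes

The experiment suite (also run by `scripts/acceptance.py`) uses problem
sizes chosen to estimate each quantity comfortably: a 32³ phantom
(~12 000 foreground voxels) for the noiseless round trip; 100 synthetic
cohorts × 13 ROIs for effect recovery; 1000 cohorts for null type-I
calibration; 200 replicates × 25 draws × 200 voxels for the noise
comparison; 1000 replicate cohorts × 68 ROIs for the null correlation
screen.

One recovery result deserves its own note: with the study's demographic
structure, patients are ~19 years older than controls, so the group
indicator and age are strongly collinear and adjusting for age inflates
the group-coefficient SE by ≈1.3×. At the 50 ms between-subject SD the
median absolute error of the recovered +80 ms group coefficient is
therefore ≈26% of the planted effect — an information limit of the
design (n = 21 with a confounded covariate), not an estimator defect; the
same estimator under age-balanced groups recovers the effect with ≈20%
median error. The null calibration of the same model is clean (type-I
error ≈0.05). The recovery experiment plants no dose effect because dose
exists only for patients: a dose slope would be group-confounded and
change the estimand of the adjusted group coefficient away from the
planted value.

## Known limitations

Ideal spoiling and mono-exponential T2* only; no inversion-recovery
reference implementation; no spatial registration or surface projection
(label-volume ROI sampling stands in for surface-based extraction); the
DAM calibration constant must come from the site; statistical models are
per-ROI OLS (no vertex-wise inference, spatial correction, or mixed
models).
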