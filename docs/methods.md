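# Methods

This note records the models, conventions and design choices behind
`dynconn`, in the order the pipeline applies them.

## Operating grain and scope

The pipeline operates on ROI-level time series: one units × time matrix per
subject, each unit mapped to a ROI of a parcellation whose ROIs carry
functional-network labels. Voxel-level image preprocessing (registration,
segmentation, normalisation, smoothing, slice timing, despiking) is out of
scope; a unit-to-ROI map supports voxel-like input, but the default and
tested grain is one unit per ROI. ROIs labelled `undefined` are removed
before any analysis (300 → 273 in the default parcellation).

## Conditioning

Order: delete initial volumes (default 10, steady-state settling) → linear
detrend per unit → nuisance regression (intercept plus any user-supplied
confound columns; motion, tissue and physiological regressors all enter
this way) → temporal band-pass 0.01–0.1 Hz. All steps are linear and
preserve the unit count and sampling interval.

**Band-pass realization.** The default filter is a zero-phase ideal
(rectangular-response) FFT band-pass with 50-sample reflect padding, the
convention of the standard ALFF tool chain. An ideal filter is exactly
amplitude-preserving in band and idempotent up to padding edge effects
(measured < 4% RMS change on double application); a forward-backward
Butterworth alternative (`design="butter"`, order 4 per pass) is retained
but re-attenuates its own transition band by ~13% RMS when reapplied, which
is why it is not the default on 190-sample series.

**Motion screening.** Framewise displacement is the Power-style scalar: sum
of absolute backward differences of the six rigid-body parameters, with
rotations converted to arc length on a 50 mm sphere. A subject is flagged
for exclusion when max translation > 2 mm, max rotation > 2°, or mean
FD > 0.5 mm.

## Dynamic metrics

**Windows.** Length 50 TR, step 10 TR; window *w* covers samples
[w·step, w·step + length); a trailing partial window is discarded, so 190
retained volumes yield 15 windows.

**ALFF.** Untapered DFT of the windowed segment (FFT length = segment
length), one-sided amplitude-calibrated spectrum: √P(f_k) = (2/N)|X_k| for
interior bins, (1/N)|X_k| at DC and Nyquist, so a unit-amplitude in-band
sinusoid contributes exactly 1 at its bin. ALFF is the mean of √P over bins
with 0.01 ≤ f ≤ 0.08 Hz, endpoints inclusive. Any fixed spectral scaling
cancels in mALFF, so the calibration is chosen to make the sinusoid oracle
exact. The ALFF band (0.01–0.08 Hz) and the conditioning band
(0.01–0.1 Hz) are independent configuration keys; dFC runs on the
0.01–0.1 Hz conditioned series.

**mALFF and windowed normalisation.** Each window's per-unit ALFF map is
divided by that window's global mean over analysis units
(`window_norm=True`, the DynamicBC convention), keeping the brain-wide mean
at exactly 1 per window; a flag switches to one common across-window
constant. Units are then averaged into ROIs (unweighted mean), and
mdALFF_mean / mdALFF_var are the across-window mean and *sample* variance
(denominator n−1; exactly 0 for a single window).

**Seed dFC.** Windowed Pearson correlations seed→target are clipped to
|r| ≤ 1 − 10⁻⁷ before atanh (unbounded Z values would corrupt downstream
means); dFC_mean / dFC_var are the across-window mean and sample variance
on the Z scale. The seed→seed entry is excluded. Seeds default to the ROIs
crossing the primary mdALFF contrast threshold (p < 0.005), overridable by
an explicit list.

## Group inference

The contrast is an ordinary least-squares GLM
`metric ~ intercept + group + age + sex + education + mean FD` (sex coded
female = 1, male = 0; group coded SCD = 1, NC = 0, so the coefficient is
SCD − NC) with a two-sided Wald t test; with exactly two groups the Tukey
post-hoc comparison coincides with this test, and a Tukey HSD branch exists
only for more than two labels. Significance tiers: p < 0.005 significant,
0.005 ≤ p < 0.01 marginal.

**FDR.** Benjamini–Hochberg step-up per family: a whole-brain family over
all 273 analysis ROIs, and network families over ROIs sharing a label. The
clinical correlation grid is corrected as one family spanning all
ROI × metric × score cells; the group-difference comparisons form their own
family.

**NBS.** Per-edge GLM t statistics are thresholded two-sided at the
critical value for the primary p (default 0.005, mirroring the edge-level
reporting threshold; exposed as config). Suprathreshold edges form
components through shared ROI endpoints; each observed component's edge
count is referred to the permutation distribution of the maximal null
component size, obtained by permuting group labels over subjects while
covariate rows stay attached (simple exchangeable scheme, not
Freedman–Lane — a documented limitation). p_fwe uses the +1 correction:
(1 + #{null ≥ observed}) / (1 + n_perm).

**Correlations.** Partial correlation residualises both variables on
[intercept, covariates] and correlates the residuals; p uses
t = r·√((n−2−k)/(1−r²)) with n−2−k degrees of freedom. The between-group
comparison uses the covariate-adjusted Fisher variance 1/(n−3−k). The
comparison defaults to two-sided with a one-sided option — the source
conventions disagree on sidedness, so the choice is explicit rather than
silent.

## Synthetic cohort generator

The generator's defaults are the study conditions: 40 SCD + 45 NC
subjects, 200 volumes at TR 2.5 s (190 after trimming), a 300-ROI atlas
(273 in 13 named networks + 27 undefined), amplitude effects at the ROIs
reported with group differences, and clinical correlation targets matching
the published grid. Phenotypes draw from the published per-group means and
SDs, clipped to printed scale ranges; covariates are group-balanced by
default, with a `confound_age` switch that couples amplitude to age for
adjustment tests.

Per subject i and ROI r:

x(t) = a_ir(t)·s_ir(t) + L·g_net(r)(t) + edge terms + σ_ε·ε(t)

where s and the per-network factors g are unit-variance white noise
brick-wall filtered to 0.01–0.08 Hz, and the envelope is

a(t) = a0 · (1 + m·sin(2π f t + φ)) / √(1 + c₂m² + c₄m⁴).

Parameter choices, with rationale:

- **f = 1/375 Hz** (period 375 s): commensurate with the sliding-window
  grid — the 15 window centres sample exactly one envelope cycle, so the
  across-window variance of the window-averaged envelope is
  a0²·(m·sinc)²/2 *independent of the random phase φ*. This makes the
  variance channel analytically controllable instead of phase-noisy.
- **Normaliser √(1 + c₂m² + c₄m⁴)** with c₂ = 0.1285, c₄ = 0.0634: cancels
  the within-window amplitude excess of a modulated carrier (leading term
  (1 − sinc²)/2), so shifting the modulation depth m moves mdALFF_var
  without moving mdALFF_mean. Calibrated against the windowed amplitude
  statistics of the canonical 50-TR window; the residual leak measured on
  full cohorts is ≈ 0.5–1% (within the 2% orthogonality contract).
- **a0 = 1 ± 0.18, m = 0.45 ± 0.35 (clipped to [0, 1.4]), network loading
  0.3, σ_ε = 0.3**: between-subject spreads large enough that group shifts
  of d between-subject SDs survive windowed estimation as comparable
  standardized effects on the measured metrics, with noise levels typical
  of ROI-averaged BOLD.

Group effects: a mean effect shifts a0 of SCD subjects by d·sd(a0); a
variance effect shifts m by d·sd(m); an edge "mean" effect shifts a
shared-signal loading (0.8 ± 0.2) between seed and target; an edge "var"
effect gates the shared signal by a random telegraph whose switching rate
scales with (1 + d/2) in SCD. Clinical targets rewrite a score as
ρ·(standardised residualised metric) + √(1−ρ²)·noise, rescaled to the
per-group reference mean/SD; with several targets on one score the weights
solve w = R⁻¹ρ (R = correlation matrix of the residualised metrics), which
reduces to the single-target formula when R = I. Integer scales clip after
rescaling — AD8's control-group range {0, 1} in particular attenuates
all-subject correlations, which is why targets are calibrated only for
|ρ| ≤ 0.6 on continuous scales.

**What the generator does and does not emulate.** It reproduces the
band-limited spectral content, network-block covariance, slow amplitude
dynamics, group effect structure, balanced covariates and score
distributions of such a cohort. It does not model hemodynamic response
shape, scanner drift or motion artefacts in image space, spatial
autocorrelation within ROIs, or non-Gaussian BOLD features; passing tests
therefore demonstrate the statistical machinery's correctness and
calibration, not performance on real scanner data.

## Known quantitative limits

With the fixed window geometry (15 windows of 50 TR, step 10 — about four
statistically independent carrier stretches, nine spectral bins per
window), subject-level mdALFF_var estimates carry irreducible estimation
noise: a shift of the modulation depth by d = 1.2 between-subject SDs
realizes as a standardized effect of ≈ 0.8 on the measured variance metric
(ceiling ≈ 0.83 with every other heterogeneity source switched off). The
variance-effect top-5 recovery rate is therefore ≈ 0.85–0.90 at the study's
sample size — the windowed-variance channel is intrinsically less sensitive
than the amplitude-mean channel (realized d ≈ 1.05, detection ≈ 1.00), a
caveat that applies equally to real sliding-window variance analyses.
Edge-level dFC effects attenuate even more strongly on the Fisher-Z scale
(windowed correlation estimates at 50 samples are noisy), so the NBS
guarantees are stated and verified at the edge-matrix level.

## Problem sizes in tests and the acceptance script

Monte-Carlo repeat counts are sized for a single CPU: null calibration uses
40 cohorts (tests) / 20 (script); effect recovery 50 / 25; NBS 20 / 10
cohorts at 200 permutations; partial-correlation recovery 100 / 50 repeats
on 12-ROI cohorts (the target is a single-ROI property, so the ROI count is
irrelevant to it). The pipeline default for NBS remains 1,000 permutations.
All stochastic procedures take explicit seeds; the pipeline manifest
records the seed, configuration hash and content hash of every output, and
re-running a completed directory with an unchanged configuration is a
no-op.
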