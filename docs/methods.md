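# Methods

This note documents the models implemented in `blursim`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical conventions a maintainer needs to know.

## Optical model

Defocus is the only aberration modeled.  It is parameterized by the
coefficient `c` (µm) of the ANSI-normalized Zernike defocus polynomial
`Z₂⁰ = √3 (2ρ² − 1)`, so `c` equals the RMS wavefront error it
contributes; "two waves of RMS" at 550 nm is `c = 1.10 µm`.  The
spherical-equivalent power is

    M = 4·√3·c / r²    (c in µm, pupil radius r in mm, M in diopters)

so two waves over a 5 mm pupil is 1.219 D.  (This quantity is sometimes
quoted rounded up to 1.25 D; the package always computes the exact value.)

The PSF is `|FFT(P)|²` of the generalized pupil function
`P = A·exp(i·2π/λ·W)` with a binary disc `A` and `W = c·√3(2ρ²−1)`,
monochromatic at λ = 550 nm.  Sampling defaults: 128 samples across the
pupil, grid padded ×4 (angular pixel `λ/(4D)` ≈ 0.095 arcmin at 5 mm),
with a guard that refuses padding below ×2 (PSF aliasing).  Correctness is
pinned to closed-form oracles: the zero-aberration PSF reproduces the Airy
first-zero radius `1.22 λ/D` within one pixel at 1.35, 3 and 5 mm pupils;
the Strehl ratio decreases strictly with defocus and is ≈ 0.8 at
`c = λ/14` (the Maréchal criterion).

Convolution of a stimulus with a PSF first resamples the PSF onto the
image's pixel grid by exact area overlap (energy- and centroid-
preserving), crops it to the support holding all but 10⁻⁸ of the energy,
and pads the image with the background luminance — the stimulus sits on an
extended uniform field, so background padding is the physically correct
boundary rule and preserves mean luminance to well under 0.1 %.  The
convolution acts on linear luminance (cd/m²); no display nonlinearity is
modeled.  Output is clipped to the input range to remove FFT ripple at the
10⁻¹² level.

## Display and stimuli

A 15° × 15° field at 15 cd/m² sampled at 0.4 arcmin/pixel (raster forced
to odd dimensions so fixation is a pixel center; origin at center,
x rightward, y upward).  The target is a dark dot (0.5 cd/m²) at 5°
eccentricity on a cardinal axis; the cue is a black ring (2.5° diameter,
1.25 arcmin thick) centered on the target location; the fixation cross is
0.5° across.  Painting uses a binary pixel-center inclusion test — no
antialiasing — which makes renders deterministic and testable by pixel
counting; a sub-pixel dot paints the single pixel nearest its center.

Locations are *retinal* quadrant labels everywhere.  The eye's optics
invert the image (nasal retina ↔ temporal field, superior ↔ inferior
field); this mapping is isolated in one function with an `eye` switch
(default `right`) to prevent silent left/right mix-ups.

Known source inconsistency: the cue is described both as 2.5° in diameter
and as extending 3.75°–7.25° from fixation (5° ± 1.25° gives 3.75°–6.25°).
The default keeps the 2.5° diameter; the discrepancy is flagged, not
resolved.

## Adaptive procedure

A 3-down-1-up transformed staircase: the level (dot diameter, arcmin)
drops by the current step factor immediately on the third consecutive
correct response and rises on every error.  Steps are multiplicative —
×1.5 until 2 reversals, ×1.122 (≈ 1 dB) thereafter; tracks start at 12
arcmin (4× a nominal 3-arcmin threshold), clamp to [0.25, 120] arcmin
(clamping is not a reversal), terminate at 12 reversals, and estimate
threshold as the geometric mean of the last 8 reversal levels — the
estimator that matches log-unit steps.  The rule's fixed point is
`p³ = ½`, i.e. 79.4 % correct.

Measured behavior of these defaults (Monte-Carlo, lapse-free Weibull
observer, β = 3): the mean estimated threshold corresponds to ≈ 78.7–78.8 %
correct — a small, stable downward bias intrinsic to finite multiplicative
steps — and one track runs ≈ 56 trials, so a 16-track session is ≈ 900
trials and a 5-session subject ≈ 4 500.  A shorter track (≈ 8 reversals)
would roughly halve the session but pushes the operating point below 78.4 %,
so the longer track was kept; trial-count tests compare the interleaved
session against independent single-track run lengths rather than a fixed
budget.  The step-size bias property (finer final steps track the target
point at least as well as coarse ones) holds asymptotically and is tested
at 30-reversal tracks; at 12 reversals a ×1.059 track has not yet finished
converging from the ×4 starting point and is transiently *more* biased.

## Synthetic observers

Detection is Bernoulli with Weibull probability
`p(x) = γ + (1−γ−λ)(1−exp(−(x/α)^β))` on dot diameter `x`; defaults
β = 3, guess rate γ = 0.02, lapse λ = 0.01.  The guess rate is a modeling
choice (the emulated task's chance level is not defined); γ = λ = 0 is
used wherever the 79.4 % fixed point must be exact.  RT (measured from
target offset) is `shift + lognormal` with median `rt_mu` (defaults:
shift 150 ms, median 400 ms, log-sd 0.2); congruent cues lower the median
by 30 ms; blur does not affect RT by construction.

Population effects are multiplicative on α (log-additive, matching the
multiplicative staircase and the ratio definition of Rx):

| effect | default | rationale |
| --- | --- | --- |
| `base_alpha` | 3.0 arcmin | clear-target threshold at 5° eccentricity; makes the generated inferior-minus-horizontal MAD difference (≈ 1.05 arcmin) the size reported for human observers |
| `location_factors` | inferior 1.35, superior 1.15, nasal/temporal 1.00 | vertical-meridian disadvantage, worst inferior |
| `blur_factors` | temporal 1.34, nasal 1.23, superior 1.07, inferior 1.03 | per-quadrant threshold inflation under 1.219 D of defocus; equals the generating refractive gain Rx of each quadrant |
| `cue_factor_incongruent` | 1.05 | marginal threshold cost of invalid cueing |
| `rt_congruency_benefit` | 30 ms | cue benefit on RT median |
| `between_subject_sd` | 0.08 | lognormal (log-sd) noise applied per subject to the base threshold and to every factor, including the RT benefit |

These defaults are generator inputs chosen to produce data with the
effect structure reported for human observers — they are conditions of
the simulation, not claims about any dataset.

## Experiment orchestration

One session = 16 fresh staircases (4 locations × {clear, blurred} ×
{congruent, incongruent}), interleaved by uniform random choice among
unfinished tracks until all terminate.  Congruency is a property of the
track, so the 50 % cue validity experienced by the subject emerges from
the balanced grid rather than per-trial randomization.  Trial timing is
virtual bookkeeping: cue onset → +50 ms cue → 66 ms ISI → 33 ms target;
RT counts from target offset; feedback is a logged field only.  Each
(subject, session) pair draws from its own stream spawned from the
experiment seed, so datasets are bit-reproducible.  Per-condition MAD is
the arithmetic mean of the 5 session estimates; per-condition RT is the
mean over correct trials (no trimming by default).

## Analysis

The three-way repeated-measures ANOVA is computed from the subject × cell
data cube by inclusion-exclusion of marginal means: each effect's
`SS` against its own effect-by-subject interaction,
`F = MS_effect / MS_{effect×subject}`, `df = ∏(levels−1)` and
`df_error = df·(n−1)`, partial η² = `SS_effect/(SS_effect+SS_error)`.
Uncorrected df are reported by default; a Greenhouse–Geisser option
computes ε on orthonormal effect-contrast scores (so single-df effects
always have ε = 1) and rescales the df for the p-value only.  Degenerate
input (zero error SS with zero effect SS) yields F = 0, p = 1.  The
implementation is verified against two independent routes: an explicit
orthonormal design-matrix projection oracle (agreement to 10⁻¹⁰) and
`statsmodels` `AnovaRM` (F and df to 10⁻⁹).

Refractive gain averages MAD over the cue factor within each blur level
before taking the per-subject, per-location ratio (matching how gains are
presented per location).  Post-hoc paired t-tests act on subject-level
marginal means with Bonferroni multiplication (capped at 1); gain tests
are two-sided one-sample t vs 1.0 per location plus a paired t between
per-subject horizontal `(nasal+temporal)/2` and vertical
`(superior+inferior)/2` means (df = n−1).  CIs are 95 % Student-t.

## Calibration and recovery (what the tests show)

- **Type-I error**: with all effect multipliers at 1, each of the 7 ANOVA
  effects rejects at α = .05 in 3–7 % of 1000 simulated experiments
  (scaled down to one session with 8-reversal tracks for runtime; ~40 s).
- **Parameter recovery**: 20 full default experiments recover each
  quadrant's generating Rx within ±0.08 and rank the horizontal meridian's
  gain above the vertical in ≥ 18/20 replicates (~5 s).

Because the generator is built from the same psychometric family the
staircase assumes, these tests validate the *pipeline* (procedure +
statistics), not the realism of human data: real observers have
non-stationary lapses, RT–accuracy interactions, fixational eye movements
and higher-order aberrations, none of which are modeled.

## Known limitations

- Monochromatic defocus only; no higher-order aberrations, chromatic
  effects, or Stiles–Crawford apodization.
- No temporal display simulation, gamma, or color; luminance is linear.
- The staircase estimator's small negative bias (≈ 0.6 points of percent
  correct at the default track length) is intrinsic to the procedure and
  left uncorrected; it cancels in threshold *ratios* such as Rx.
- The RM-ANOVA assumes a complete balanced factorial; missing cells raise
  an error rather than being imputed.
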