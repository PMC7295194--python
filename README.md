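# blursim

Simulated psychophysics of defocus-blur correction at isoeccentric retinal
locations under exogenous spatial cueing.

## The problem

How much does removing optical blur help detection, and is the benefit the
same everywhere in the visual field?  In the experiment this package
simulates, observers detect a small dark dot flashed at 5° eccentricity in
one of the four cardinal retinal quadrants (temporal, nasal, superior,
inferior), preceded by a brief ring cue that is either *congruent* (same
quadrant) or *incongruent* (radially opposite).  Targets are shown either
sharp or blurred by a known amount of defocus, and detection thresholds are
measured adaptively.  The quantities of interest are:

- **MAD** (minimum angle of detection): the threshold dot diameter in
  arcmin at which detection reaches the staircase's target performance;
- **refractive gain** `Rx = MAD_blur / MAD_clear`: how much blur inflates
  the threshold (values above 1 quantify the benefit of correcting it);
- cue effects on response time (RT) and threshold.

`blursim` reproduces this experiment in silico end to end, for five
simulated subjects, so that the full analysis chain — optics, adaptive
procedure, factorial design, repeated-measures statistics — can be tested
against known ground truth.

## What is inside

| module | contents |
| --- | --- |
| `blursim.optics` | Zernike defocus ⇄ diopters (`M = 4√3·c/r²`), generalized pupil function, PSF via `|FFT(pupil)|²`, Strehl ratio, area-preserving PSF resampling, luminance-preserving convolution |
| `blursim.stimuli` | calibrated 15 cd/m², 15°×15° raster at 0.4 arcmin/px; fixation cross, dark dot target, ring cue; retinal-quadrant ⇄ visual-field mapping |
| `blursim.staircase` | 3-down-1-up transformed staircase (converges at `p³ = ½`, i.e. 79.4 % correct), multiplicative steps ×1.5 → ×1.122, reversal-based threshold (geometric mean of last 8 reversals), random interleaving |
| `blursim.observer` | synthetic subjects: Weibull psychometric function `p = γ + (1−γ−λ)(1−e^{−(x/α)^β})`, shifted-lognormal RT with a congruency benefit, multiplicative population effects with lognormal between-subject noise |
| `blursim.experiment` | 16 interleaved staircases per session (4 locations × 2 blur × 2 cue), 5 sessions × 5 subjects, virtual trial timing (cue 50 ms → ISI 66 ms → target 33 ms), reproducible from a single seed |
| `blursim.analysis` | three-way repeated-measures ANOVA (`F = MS_effect / MS_{effect×subject}`, partial η²), Bonferroni post-hocs, refractive gains with one-sample and meridian-paired t-tests |

## Worked example

```python
import numpy as np
from blursim import (
    ExperimentConfig, ObserverEffects, make_cohort, run_experiment,
    compute_tables, rm_anova_threeway, refractive_gain, gain_tests,
)

rng = np.random.default_rng(11)
cohort = make_cohort(ObserverEffects(), n_subjects=5, rng=rng)
dataset = run_experiment(ExperimentConfig(seed=11), cohort)

table = compute_tables(dataset)              # 5 subjects x 16 cells
anova = rm_anova_threeway(table, dv="mad")
gains = refractive_gain(table)
```

prints (via the report helpers):

```
location:      F(3,12) = 6.694, p = 0.0066, partial eta^2 = 0.626
blur:          F(1,4) = 120.706, p = 0.0004, partial eta^2 = 0.968
location:blur: F(3,12) = 23.565, p = 0.0000, partial eta^2 = 0.855
mean Rx: {'inferior': 0.993, 'nasal': 1.282, 'superior': 1.023, 'temporal': 1.369}
horizontal vs vertical: diff = 0.317, t(4) = 8.18, p = 0.0012
```

Read this as: detection thresholds differ across quadrants and are strongly
inflated by blur, the inflation itself differs by quadrant
(location × blur interaction), and the refractive gain is large on the
horizontal meridian (temporal 1.37, nasal 1.28) but near 1.0 on the
vertical meridian — blur correction buys little there.  These recovered
gains sit close to the cohort's generating blur factors
(1.34 / 1.23 / 1.07 / 1.03), which is the point of the simulation: the
pipeline's estimates are faithful to known ground truth.

A command-line front end wraps the same library:

```bash
blursim simulate --seed 5 --out-dir run1     # trials.csv, thresholds.csv, cohort.csv
blursim analyze  --data-dir run1             # ANOVA/post-hoc/gain tables + report
blursim render   --location superior --blurred --out-dir frames
blursim recover  --replicates 20 --seed 2    # parameter-recovery summary
```

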