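# gradedsdt

Signal-detection analysis of graded near-threshold perception.

When listeners rate their perception of a faint tone on a six-point scale,
unequal-variance signal detection theory (SDT) predicts not only the rating
frequencies but also the *mean internal evidence* behind every rating — and
therefore the graded amplitude of any neural readout (auditory-cortex
response, pupil dilation) that tracks that evidence. This package implements
that analysis end to end for psychophysicists and cognitive
neuroscientists: criterion estimation from rating tables, grand-average
fitting of the evidence model, per-rating amplitude prediction, two
competitor accounts (a bimodal "bifurcation" model and a hard threshold
model), the supporting behavioral metrics (predictive values, arousal
quintiles, vigilance splits), a pupillometry preprocessing chain, and the
group-level waveform statistics (temporal cluster permutation tests,
polynomial contrasts, repeated-measures ANOVA). A synthetic-data module
generates every input under the model's own generative assumptions, so the
whole pipeline is testable without any recordings.

## The model

Evidence on a latent axis is Gaussian per trial class,

    noise  ~ N(mu_noise = 0, sigma_noise = 1)        (convention)
    signal ~ N(mu_signal,    sigma_signal)

A six-point rating scale corresponds to five ordered decision criteria
c_1 < ... < c_5; rating i is given when the evidence falls in (c_{i-1}, c_i]
with c_0 = -inf, c_6 = +inf. The machinery:

* criterion from binary rates: `c = -(z(H) + z(FA)) / 2`; sensitivity
  `d' = z(H) - z(FA)`;
* `sigma_noise / sigma_signal` is the slope of the z-transformed
  rating ROC; `mu_signal` is chosen so that the criteria implied by the
  noise-side and signal-side cumulative rating probabilities agree
  (solving `P(X > c_i) = p_i` per class);
* the predicted mean amplitude of rating i is the truncated-Gaussian mean
  `A_i = mu + sigma * (phi(a) - phi(b)) / (Phi(b) - Phi(a))` on the bin
  `(c_{i-1}, c_i]`;
* profiles are normalized by shifting the noise-class rating-1 amplitude to
  0 and dividing by the post-shift signal-class rating-1 amplitude (A_H1),
  then compared with measured per-rating amplitudes via R².

The bifurcation variant replaces the signal distribution by a two-mode
mixture `(1-beta) N(0,1) + beta N(mu_high, 1)` with `beta` set to the
dichotomized detection rate; the threshold variant zeroes predicted
amplitudes for sub-threshold ratings (1–3 by default).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (defaults: 17 participants, 500 signal-present + 100 signal-absent
trials each, signal N(1.385, 1.344), criteria jittered across participants):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_behavior.py
python analysis/03_fit_sdt.py
python analysis/04_compare_models.py
python analysis/05_pupil.py --seed 1
python analysis/06_waveform_stats.py --seed 1
```

Output of `02_behavior.py` (seed 1):

```
group means (N=17): H=54.8%, FA=12.0%, c=0.57 (SD 0.30), d'=1.38
PPV by rating: [0.27 0.42 0.5  0.66 0.8  0.96]
NPV by rating: [0.73 0.58 0.5  0.34 0.2  0.04]
```

The dichotomized hit rate (ratings 4–6 counted as "present") sits near 55%
with a moderate criterion c ≈ 0.6, and the positive predictive value rises
monotonically with rating — the behavioral signature of graded, criterion-
based reporting. `03_fit_sdt.py` then prints:

```
fitted evidence model: mu_signal=1.339, sigma_signal=1.395 (delta-mu/delta-sigma = 3.39)
R^2 = -2.363
```

The recovered parameters are close to the generating values (1.385, 1.344).
The R² against the measured per-rating amplitudes is volatile across seeds
because the A_H1 normalization divides by a small anchor (see
`docs/methods.md`); `04_compare_models.py` shows that the three accounts are
nevertheless consistently ordered, with the threshold model explaining the
least variance and the fitted unimodal and bimodal signal densities nearly
identical:

```
unequal_variance_sdt     R^2 = -2.363
bimodal_bifurcation      R^2 = -2.271
threshold                R^2 = -2.465
unimodal vs bimodal signal-density similarity: Pearson r = 0.973
```

`05_pupil.py` preprocesses simulated 1000 Hz pupil traces (blink
interpolation, 4 Hz low-pass, epoching, >20% interpolation rejection) and
shows the pupil dilation response derivative (PDR', 500–1000 ms window)
growing with rating; `06_waveform_stats.py` finds a significant negative
cluster (100–400 ms) for every rating and a strong linear amplitude trend.

The same stages are available as a single command (`gradedsdt all --seed 1`)
or programmatically through `gradedsdt.pipeline.run_pipeline`, which writes
all artifacts plus a checksummed manifest.

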