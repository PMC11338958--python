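# Methods

## The evidence model and its estimation

Each trial produces a latent evidence value: `N(0, 1)` on signal-absent
trials (by convention) and `N(mu_signal, sigma_signal^2)` on signal-present
trials. A six-point perceptual rating corresponds to five ordered decision
criteria on this axis; the observer reports rating i when the evidence falls
in `(c_{i-1}, c_i]`.

Estimation proceeds in the staged order the analysis modules implement:

1. **SD ratio.** The cumulative rating ROC is z-transformed; under the model
   `z(H_k) = mu_signal/sigma_signal + z(FA_k) * sigma_noise/sigma_signal`,
   so the line's slope estimates `sigma_noise/sigma_signal`. When the ROC
   carries backing trial counts the line is fitted by weighted least squares
   with errors in both coordinates (York's iteration, binomial delta-method
   variances `p(1-p) / (N phi(z)^2)`). Plain OLS treats the extreme ROC
   points — which have by far the largest z-variance — as exact and pays for
   it with attenuation bias and roughly twice the sampling SD at this
   design's trial counts; the weighted fit reduces the SD of the recovered
   `sigma_signal` from ~0.09 to ~0.05 at 17×600 trials. Inputs without
   counts (exact probabilities) use OLS, where the z-ROC is exactly linear.
2. **Signal mean.** Criteria implied by the noise side
   (`c_i = Phi^{-1}(1 - FA_i)`) and by the signal side
   (`c_i = mu + sigma_signal Phi^{-1}(1 - H_i)`) must coincide on noiseless
   data; `mu_signal` minimizes the summed absolute difference between the
   two criterion sets (grid prescan on [0, 5], Brent refinement, tolerance
   1e-6). Both steps run on grand-average probabilities (per-participant
   probability vectors averaged), which pools noisy per-participant tables
   at the cost of a heterogeneity bias discussed below.
3. **Per-participant criteria.** Given the fitted model, each `c_i`
   independently minimizes
   `|P_noise(X > c) - p_FA,i| + |P_signal(X > c) - p_H,i|` over [-6, 6]
   (grid prescan + bounded Brent; ties within 1e-10 break toward the
   noise-only solution, so exact data reproduce the generating criteria to
   the optimizer tolerance). Criterion inversions are repaired by isotonic
   pooling of adjacent violators with an epsilon ladder and flagged;
   solutions at the search bounds are flagged too.
4. **Amplitude prediction.** The model's mean amplitude for rating i is the
   truncated-Gaussian conditional mean on `(c_{i-1}, c_i]`, in closed form
   `mu + sigma (phi(a) - phi(b)) / (Phi(b) - Phi(a))`. Bins with mass below
   1e-12 return the (clipped) bin midpoint and carry a `degenerate` flag —
   never a silent NaN — and are excluded from any fit statistic when the
   measured side is also missing.

All rates entering z-transforms are clipped to `[1/(2N), 1 - 1/(2N)]` with N
the backing trial count (fixed 1e-6 floor when no count exists); clipping is
logged.

## Normalization and R²

Predicted and measured amplitudes live in different units, so both are
mapped to a common dimensionless scale: subtract the across-participant mean
of the noise-class rating-1 amplitude (anchoring it to 0), then divide by
the post-shift signal-class rating-1 amplitude, A_H1 (anchoring it to 1).
R² = 1 - SS_res/SS_tot is computed over the concatenated noise+signal
per-rating means that have measured data.

Two deliberate choices here:

* **Group-level normalization.** Profiles are averaged raw across
  participants and normalized once. Normalizing per participant first is
  unstable under realistic criterion spread: a participant whose lowest
  criterion sits near the noise mean has a post-shift A_H1 near (or below)
  zero, and dividing by it explodes.
* **A shared scale for competitor models.** All three models place their
  noise distribution at N(0, 1), so their predictions share units. The
  bimodal model's own A_H1 is structurally close to zero (its rating-1
  signal trials come almost entirely from the noise-like lower mode), so
  competitor predictions are divided by the primary unimodal fit's divisor
  rather than their own. The A_H1 interpretation itself (signal-class
  rating-1 amplitude after shifting) is configurable in
  `normalize_profiles`.

Even so, R² inherits a known volatility: A_H1 is a small difference of two
truncated means (~0.17 evidence units under the default design against an
amplitude range of ~4), so a fitted `sigma_signal` off by 0.05 rescales the
whole predicted profile by tens of percent. Across seeds the unequal-
variance R² is typically ~0.8 but occasionally strongly negative; the
*ordering* of the models (threshold worst, bimodal ≈ unimodal) and the
near-identity of the fitted unimodal and bimodal signal densities
(Pearson r ≈ 0.95–0.97 on a [-4, mu+4 sigma] grid) are stable. R² on these
synthetic runs measures estimation error amplified by the anchor, not model
misspecification, and should be read accordingly.

## Competitor models

* **Bifurcation (bimodal) model.** Signal evidence is
  `(1-beta) N(mu_low, sigma) + beta N(mu_high, sigma)` with
  `sigma = sigma_noise = 1` shared by all components. `beta` is not fitted:
  it is the group dichotomized detection rate (ratings 4–6 = detected)
  rounded to two decimals. `mu_low` is pinned to the noise mean (0), so only
  `mu_high` is searched, with the same criterion-consistency objective; the
  mixture tail has no closed-form quantile and is inverted by bracketed
  root-finding (tolerance 1e-8; the tail is strictly decreasing, so the
  root is unique). `beta = 0` makes signal and noise identical and returns
  a fit flagged `unidentifiable`.
* **Threshold model.** The fitted Gaussian model, with normalized predicted
  amplitudes of ratings at or below the threshold (default between ratings
  3 and 4, configurable) set to zero: sub-threshold trials are assumed to
  evoke no perception-related response.

## Behavioral metrics

Dichotomization pools ratings above a cut (default 3) into "present".
Per-rating positive/negative predictive values use per-rating response
rates normalized by the class totals, `PPV_r = HR_r/(HR_r + FAR_r)` and
`NPV_r = CRR_r/(CRR_r + MR_r)`; PPVs assume a threshold below rating 1 and
NPVs above rating 6, which makes each value invariant to any dichotomization
threshold on its side. Zero denominators yield NaN, never 0. The arousal
analysis sorts each participant's signal trials by pre-stimulus baseline
pupil size (stable sort, chronological tie-break), splits them into five
equal-count bins (remainder trials go one each to the lowest bins), and
averages per-bin detection rates across participants; the vigilance analysis
does the same over five consecutive chronological parts.

## Pupil preprocessing

1000 Hz pupil-area traces are processed as: linear blink interpolation
padded 100 ms on each side (chord between the first clean samples outside
the pad; edge blinks hold the clean-side value, with a warning); 4 Hz
low-pass — realized as a 2nd-order Butterworth applied forward-backward,
because phase distortion from a causal filter would bias the derivative's
latencies; epoching from -500 to +3000 ms; rejection of epochs whose
interpolated fraction exceeds 20% (the rule is exact: fraction > 0.20 iff
rejected); divisive baseline by the mean over -200–0 ms (output baseline
mean exactly 1). The pupil dilation response derivative (PDR') is the
sample-to-sample first difference of the *unbaselined* epoch, smoothed with
a 200-sample centered moving mean (shrinking at the edges to preserve epoch
length), optionally corrected by subtracting its own -200–0 ms mean, which
removes a linear pre-stimulus trend — needed when a noise onset ~1 s before
the target drives a global rise. The PDR' analysis window is 500–1000 ms.

## Waveform statistics

The temporal cluster permutation test is the one-sample (sign-flip) variant:
paired differences (or the condition itself for tests against zero) are
reduced to pointwise t values inside the analysis window (auditory cortex
100–400 ms, posterior/retrosplenial 300–800 ms, pupil 500–1000 ms);
contiguous runs exceeding the two-sided alpha = 0.05 t threshold form
clusters scored by summed t; positive and negative clusters are pooled by
absolute mass; the family-wise null is the maximum absolute cluster mass
under random within-participant sign flips (default 10 000 permutations,
configurable), and cluster p-values use the `(1 + count) / (1 + n_perm)`
convention. The implementation is vectorized across permutations (sign
flips only change column sums, not sums of squares), which makes large
calibration studies cheap. Polynomial contrasts apply orthonormal
linear/quadratic weights per participant and test the scores against zero
(F = t², df = (1, n-1)). The one-way repeated-measures ANOVA with
Greenhouse-Geisser correction is delegated to `pingouin.rm_anova`.
Stimulus-free reference epochs are cut 1.9–3.0 s after each onset (with
2.0 s mapped to t = 0), usable as extra signal-absent trials when onsets
are at least 3 s apart.

## Synthetic data: what it emulates, and what it does not

The generator draws trial evidence from the configured class distributions,
produces ratings via per-participant criteria (group criteria plus i.i.d.
Gaussian jitter, re-sorted), and links measured amplitude to evidence by
identity plus additive Gaussian noise — the minimal assumption under which
within-rating amplitude means converge to the truncated-Gaussian
predictions. Pupil traces are baseline + slow sinusoidal drift + an
event-locked dilation kernel `(t/t_max)^n exp(n(1 - t/t_max))`
(n = 10.1, t_max = 930 ms, so dilation rises from ~500 ms and peaks near
1 s) with gain increasing in trial evidence, plus white noise and annotated
blinks. Group waveforms are a negative-going early component (center 300 ms)
scaled by condition-mean evidence plus a late positive component for high
ratings, with participant noise shrinking as 1/sqrt(trials averaged).

Defaults mirror the rating study design: 17 participants, 500 signal-present
and 100 signal-absent trials each (two session halves of 250 + 50), signal
N(1.385, 1.344); group criteria (0.4, 0.8, 1.2, 1.7, 2.3) chosen so the
middle criterion yields a dichotomized hit rate near 0.55, false alarms near
0.12 and criterion c ≈ 0.55 with jitter SD 0.4 matching the observed
between-participant criterion spread; amplitude noise SD 0.5. The binary-
detection design (150 near-threshold, 50 absent, 50 distractor trials per
run) is available through the same config. All generators are pure
functions of (config, seed); per-stream child generators are derived
deterministically from the master seed.

What the synthetic data does *not* contain: real neural or pupillary
physiology (kernels and templates are phenomenological), serial
dependencies or criterion drift within a session, lapses or finger errors,
non-Gaussian evidence, and any mismatch between the evidence the observer
uses and the amplitude the "recording" reflects. Passing tests therefore
demonstrate that the estimators invert their own generative assumptions and
that the statistics are calibrated — not that real recordings satisfy those
assumptions.

## Known limitations

* **Heterogeneity bias of the grand-average fit.** Averaging rating
  probabilities across participants with criterion jitter of SD `s` is
  equivalent to convolving both class distributions with that jitter
  (variances inflate by s²). At the default jitter (0.4) this biases the
  recovered `mu_signal` by about -0.05 and `sigma_signal` by about -0.03,
  on top of sampling SD ~0.03–0.05 at 17×600 trials. Parameter-recovery
  checks at tolerance 0.05 under these conditions are therefore near the
  edge of what the procedure can deliver; this is a property of
  grand-average estimation under heterogeneity, not of the implementation.
* **A_H1 anchor sensitivity** of R², discussed above.
* The search bounds for `mu_signal` ([0, 5]) and criteria ([-6, 6]) assume
  near-threshold designs; far-suprathreshold data need wider bounds.
* The cluster test corrects family-wise error over time within one window
  only; no spatial clustering is implemented.
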