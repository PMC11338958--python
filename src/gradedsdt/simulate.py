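"""Synthetic data generator for the full analysis pipeline.

Generates every input the other modules consume — trial-level rating tables,
per-trial amplitudes, continuous pupil traces with blinks, and group
waveforms — under the same generative assumptions the analysis makes:

* internal evidence is Gaussian, N(0, 1) for signal-absent trials and
  N(mu_signal, sigma_signal^2) for signal-present trials (or the bimodal
  mixture variant);
* ratings arise from five ordered criteria on the evidence axis, jittered
  per participant and re-sorted;
* a measured amplitude is the trial's evidence plus measurement noise
  (so within-rating amplitude means converge to truncated-Gaussian means);
* the pupil trace is a slow drift plus an event-locked dilation kernel whose
  gain grows with trial evidence, plus annotated blinks and white noise;
* group waveforms are a negative-going auditory component (AAN-like,
  ~150-700 ms) scaled by condition-mean evidence plus a late positive
  component for high ratings.

Default design constants follow the rating experiment that the analysis
targets: 17 participants with 500 signal-present and 100 signal-absent
trials each (two parts of 250 + 50), single SNR; the binary-detection design
uses 150 near-threshold, 50 absent, and 50 distractor trials per run.

All generators are pure functions of (config, seed): per-stream child seeds
are derived deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sdt_core import CriterionSet, GaussianSdtModel
from .model_variants import BimodalSignalModel
from .pupil import PupilTrace
from .waveforms import WaveformSet

#: group-level criteria consistent with the default model: the middle
#: criterion yields a dichotomized hit rate near 0.55 and criterion c ~ 0.5
DEFAULT_CRITERIA = (0.4, 0.8, 1.2, 1.7, 2.3)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment, with study-matched defaults."""

    # evidence model (unimodal Gaussian unless a bimodal model is passed)
    mu_signal: float = 1.385
    sigma_signal: float = 1.344
    bimodal: BimodalSignalModel | None = None
    criteria: tuple = DEFAULT_CRITERIA

    # rating-experiment design
    n_participants: int = 17
    n_present: int = 500
    n_absent: int = 100
    n_parts: int = 2  # session halves (250 + 50 trials each by default)

    # binary-detection design (per run)
    n_nt: int = 150
    n_absent_run: int = 50
    n_am: int = 50

    # between-participant variability and the evidence-amplitude link
    criterion_jitter_sd: float = 0.4
    amplitude_noise_sd: float = 0.5

    # baseline pupil and optional arousal-evidence coupling
    baseline_pupil_mean: float = 800.0
    baseline_pupil_sd: float = 60.0
    pupil_evidence_coupling: float = 0.0

    # event-locked pupil dilation kernel (Hoeks-Levelt form), 1000 Hz
    pupil_fs: float = 1000.0
    kernel_n: float = 10.1
    kernel_tmax_ms: float = 930.0
    kernel_gain: float = 20.0
    kernel_gain_per_evidence: float = 8.0
    trial_interval_ms: float = 3000.0
    pupil_noise_sd: float = 1.0
    drift_amplitude: float = 15.0
    blink_rate_hz: float = 0.1
    blink_duration_ms: tuple = (100.0, 250.0)

    # group waveform templates (ms, arbitrary units)
    waveform_fs: float = 500.0
    waveform_window_ms: tuple = (-200.0, 1200.0)
    aan_center_ms: float = 300.0
    aan_width_ms: float = 140.0
    aan_gain: float = -2.0          # negative-going, per unit mean evidence
    p3_center_ms: float = 500.0
    p3_width_ms: float = 90.0
    p3_gain: float = 1.5            # added for ratings >= 5
    waveform_noise_sd: float = 0.3

    def model(self) -> GaussianSdtModel:
        return GaussianSdtModel(self.mu_signal, self.sigma_signal)

    def criterion_set(self) -> CriterionSet:
        return CriterionSet(np.asarray(self.criteria, dtype=float))


def _child(seed, *key) -> np.random.Generator:
    """Deterministic per-stream generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _draw_evidence(rng, cfg: SimulationConfig, n: int, present: bool) -> np.ndarray:
    if not present:
        return rng.standard_normal(n)
    if cfg.bimodal is not None:
        m = cfg.bimodal
        hi = rng.random(n) < m.beta
        mu = np.where(hi, m.mu_high, m.mu_low)
        return mu + m.sigma_common * rng.standard_normal(n)
    return cfg.mu_signal + cfg.sigma_signal * rng.standard_normal(n)


def simulate_rating_experiment(cfg: SimulationConfig, seed: int
                               ) -> tuple[pd.DataFrame, dict]:
    """Simulate the six-point rating experiment.

    Returns a tidy trial table (participant_id, condition, rating, evidence,
    run, trial_index, baseline_pupil) plus the ground truth (model, group
    criteria, per-participant criteria) for recovery tests.
    """
    group_criteria = np.asarray(cfg.criteria, dtype=float)
    frames = []
    per_participant_criteria = {}
    for p in range(cfg.n_participants):
        rng = _child(seed, 1, p)
        crit = np.sort(group_criteria
                       + cfg.criterion_jitter_sd * rng.standard_normal(group_criteria.size))
        # guard against exact ties after sorting
        for k in range(1, crit.size):
            if crit[k] <= crit[k - 1]:
                crit[k] = crit[k - 1] + 1e-9
        per_participant_criteria[p] = crit
        n_total = cfg.n_present + cfg.n_absent
        present = np.zeros(n_total, dtype=bool)
        present[:cfg.n_present] = True
        rng.shuffle(present)
        baseline = cfg.baseline_pupil_mean \
            + cfg.baseline_pupil_sd * rng.standard_normal(n_total)
        evidence = np.where(
            present,
            _draw_evidence(rng, cfg, n_total, True),
            _draw_evidence(rng, cfg, n_total, False))
        if cfg.pupil_evidence_coupling:
            z = (baseline - cfg.baseline_pupil_mean) / cfg.baseline_pupil_sd
            evidence = evidence + cfg.pupil_evidence_coupling * z
        rating = 1 + np.searchsorted(crit, evidence)
        part_size = n_total // cfg.n_parts
        run = np.minimum(np.arange(n_total) // part_size, cfg.n_parts - 1) + 1
        frames.append(pd.DataFrame({
            "participant_id": p,
            "condition": np.where(present, "signal", "absent"),
            "rating": rating.astype(int),
            "evidence": evidence,
            "run": run.astype(int),
            "trial_index": np.arange(n_total),
            "baseline_pupil": baseline,
            "valid": True}))
    trials = pd.concat(frames, ignore_index=True)
    truth = {"model": cfg.model() if cfg.bimodal is None else cfg.bimodal,
             "group_criteria": group_criteria,
             "criteria": per_participant_criteria,
             "seed": seed}
    return trials, truth


def simulate_trial_amplitudes(trials: pd.DataFrame, noise_sd: float,
                              seed: int) -> pd.DataFrame:
    """Attach a measured amplitude = latent evidence + N(0, noise_sd^2)."""
    if "evidence" not in trials.columns:
        raise ValueError("trials lack the latent 'evidence' column")
    rng = _child(seed, 2)
    out = trials.copy()
    out["amplitude"] = out["evidence"].to_numpy() \
        + noise_sd * rng.standard_normal(len(out))
    return out


def pupil_kernel(cfg: SimulationConfig, duration_ms: float = 3000.0) -> np.ndarray:
    """Event-locked dilation kernel h(t) = (t/tmax)^n exp(n (1 - t/tmax)).

    Unit peak at ``kernel_tmax_ms`` (930 ms by default, matching a dilation
    that rises from ~500 ms and peaks near 1 s).
    """
    t = np.arange(0, duration_ms, 1000.0 / cfg.pupil_fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (t / cfg.kernel_tmax_ms) ** cfg.kernel_n \
            * np.exp(cfg.kernel_n * (1.0 - t / cfg.kernel_tmax_ms))
    h[0] = 0.0
    return h


def simulate_pupil_traces(trials: pd.DataFrame, cfg: SimulationConfig,
                          seed: int, participants=None) -> dict[int, PupilTrace]:
    """Continuous 1000 Hz pupil traces per participant.

    Each trace is a baseline + slow sinusoidal drift + one dilation kernel per
    trial (gain = kernel_gain + kernel_gain_per_evidence * evidence) + white
    noise + annotated blinks (samples driven to zero).  Trial onsets are
    spaced ``trial_interval_ms`` apart in the participant's chronological
    trial order.
    """
    out = {}
    iti = int(round(cfg.trial_interval_ms * cfg.pupil_fs / 1000.0))
    kern = pupil_kernel(cfg, duration_ms=cfg.trial_interval_ms)
    pre = int(round(1.0 * cfg.pupil_fs))  # 1 s lead-in before the first trial
    for p, sub in trials.groupby("participant_id"):
        if participants is not None and p not in participants:
            continue
        sub = sub.sort_values("trial_index")
        rng = _child(seed, 3, p)
        n_trials = len(sub)
        n_samples = pre + n_trials * iti + iti
        t = np.arange(n_samples) / cfg.pupil_fs
        trace = np.full(n_samples, cfg.baseline_pupil_mean, dtype=float)
        trace += cfg.drift_amplitude * np.sin(2 * np.pi * 0.05 * t
                                              + rng.uniform(0, 2 * np.pi))
        onsets = pre + np.arange(n_trials) * iti
        gains = cfg.kernel_gain \
            + cfg.kernel_gain_per_evidence * sub["evidence"].to_numpy()
        for onset, g in zip(onsets, gains):
            stop = min(onset + kern.size, n_samples)
            trace[onset:stop] += g * kern[:stop - onset]
        if cfg.pupil_noise_sd > 0:
            trace += cfg.pupil_noise_sd * rng.standard_normal(n_samples)
        blinks = []
        if cfg.blink_rate_hz > 0:
            n_blinks = rng.poisson(cfg.blink_rate_hz * n_samples / cfg.pupil_fs)
            for _ in range(n_blinks):
                dur = int(rng.uniform(*cfg.blink_duration_ms)
                          * cfg.pupil_fs / 1000.0)
                start = int(rng.integers(0, max(n_samples - dur - 1, 1)))
                trace[start:start + dur] = 0.0
                blinks.append((start, start + dur - 1))
        out[p] = PupilTrace(samples=trace, fs=cfg.pupil_fs,
                            blinks=sorted(blinks), onsets=onsets)
    return out


def _gauss_bump(times_ms: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - center) / width) ** 2)


def simulate_group_waveforms(trials: pd.DataFrame, cfg: SimulationConfig,
                             seed: int) -> dict[str, WaveformSet]:
    """Per-rating condition-mean waveforms for every participant.

    The negative-going early component scales with the condition's mean
    evidence; a late positive component is added for high ratings (>= 5).
    Participant noise shrinks with the number of trials averaged, as it would
    for a condition mean.  Conditions with no trials for a participant get a
    pure-noise waveform at the single-trial noise level.
    """
    dt = 1000.0 / cfg.waveform_fs
    times = np.arange(cfg.waveform_window_ms[0], cfg.waveform_window_ms[1], dt)
    aan = _gauss_bump(times, cfg.aan_center_ms, cfg.aan_width_ms)
    aan[times < 0] = 0.0
    p3 = _gauss_bump(times, cfg.p3_center_ms, cfg.p3_width_ms)
    p3[times < 0] = 0.0
    out = {}
    signal = trials[trials["condition"] == "signal"]
    participants = sorted(trials["participant_id"].unique())
    for rating in range(1, 7):
        rows = []
        for p in participants:
            rng = _child(seed, 4, p, rating)
            sub = signal[(signal["participant_id"] == p)
                         & (signal["rating"] == rating)]
            n = max(len(sub), 1)
            mean_ev = float(sub["evidence"].mean()) if len(sub) else 0.0
            wav = cfg.aan_gain * mean_ev * aan
            if rating >= 5:
                wav = wav + cfg.p3_gain * p3
            wav = wav + cfg.waveform_noise_sd / np.sqrt(n) \
                * rng.standard_normal(times.size)
            rows.append(wav)
        out[f"rating_{rating}"] = WaveformSet(data=np.vstack(rows),
                                              times_ms=times,
                                              condition=f"rating_{rating}")
    return out


def simulate_evoked_stream(cfg: SimulationConfig, seed: int,
                           n_onsets: int = 50, fs: float = 500.0,
                           soa_s: tuple = (3.0, 5.0),
                           peak: float = 1.0,
                           decay_ms: float = 300.0,
                           noise_sd: float = 0.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous stream of exponentially decaying evoked responses.

    Suitable input for :func:`gradedsdt.waveforms.build_reference_epochs`:
    onsets are spaced 3-5 s apart and each evokes peak * exp(-t/decay).
    Returns (stream, onset sample indices).
    """
    rng = _child(seed, 5)
    soas = rng.uniform(soa_s[0], soa_s[1], size=n_onsets)
    onsets = (np.cumsum(np.concatenate(([1.0], soas[:-1]))) * fs).astype(int)
    n_samples = int(onsets[-1] + soa_s[1] * fs)
    stream = np.zeros(n_samples)
    t = np.arange(int(2.0 * fs)) / fs * 1000.0
    kern = peak * np.exp(-t / decay_ms)
    for onset in onsets:
        stop = min(onset + kern.size, n_samples)
        stream[onset:stop] += kern[:stop - onset]
    if noise_sd > 0:
        stream += noise_sd * rng.standard_normal(n_samples)
    return stream, onsets
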