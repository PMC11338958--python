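"""Pupillometry preprocessing: blinks, filtering, epoching, baseline, PDR'.

The pipeline mirrors standard pupillometric practice for event-related
designs sampled at 1000 Hz:

1. blink correction by linear interpolation, padded 100 ms on each side;
2. 4 Hz zero-phase low-pass of the continuous trace;
3. epoching from -500 to +3000 ms around stimulus onset;
4. rejection of epochs with more than 20% interpolated samples;
5. divisive baseline correction (mean over -200..0 ms);
6. the pupil dilation response derivative PDR': first difference of the
   *unbaselined* epoch, smoothed with a 200-sample centered moving mean,
   optionally baseline-corrected by subtracting its own -200..0 ms mean
   (which linearly removes slow pre-stimulus drift).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

BASELINE_WINDOW_MS = (-200.0, 0.0)
REJECT_THRESHOLD = 0.20


@dataclass
class PupilTrace:
    """Continuous pupil-area recording with blink and event annotations.

    ``blinks`` is a list of (start, end) sample indices (inclusive) and
    ``onsets`` the stimulus-onset sample indices.
    """

    samples: np.ndarray
    fs: float = 1000.0
    blinks: list = field(default_factory=list)
    onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        n = self.samples.size
        for s, e in self.blinks:
            if not (0 <= s <= e < n):
                raise ValueError(f"blink ({s}, {e}) outside trace bounds")


@dataclass
class PupilEpoch:
    """Event-locked pupil segment with bookkeeping for rejection and state."""

    samples: np.ndarray
    times_ms: np.ndarray
    interpolated_fraction: float = 0.0
    baseline_value: float = np.nan
    state: str = "raw"  # raw | divisive_baselined | derivative
    rejected: bool = False
    onset_index: int = -1

    def baseline_mask(self) -> np.ndarray:
        lo, hi = BASELINE_WINDOW_MS
        return (self.times_ms >= lo) & (self.times_ms < hi)


def interpolate_blinks(trace: PupilTrace, pad_ms: float = 100.0
                       ) -> tuple[PupilTrace, np.ndarray]:
    """Replace blink segments (padded by ``pad_ms``) with straight lines.

    Samples in [start - pad, end + pad] are replaced by the chord between the
    first clean samples just outside the padded interval; a boolean mask marks
    every replaced sample.  Pads that reach past a trace edge fall back to
    holding the value of the clean side, with a warning.
    """
    x = trace.samples.copy()
    n = x.size
    pad = int(round(pad_ms * trace.fs / 1000.0))
    mask = np.zeros(n, dtype=bool)
    for start, end in trace.blinks:
        i0 = start - pad
        i1 = end + pad
        left = i0 - 1
        right = i1 + 1
        i0c, i1c = max(i0, 0), min(i1, n - 1)
        if left < 0 and right > n - 1:
            warnings.warn("blink pad covers the whole trace; holding nothing")
            continue
        if left < 0:
            warnings.warn("blink pad reaches trace start; holding right value")
            x[i0c:i1c + 1] = x[right]
        elif right > n - 1:
            warnings.warn("blink pad reaches trace end; holding left value")
            x[i0c:i1c + 1] = x[left]
        else:
            idx = np.arange(i0, i1 + 1)
            x[i0:i1 + 1] = np.interp(idx, [left, right], [x[left], x[right]])
        mask[i0c:i1c + 1] = True
    out = PupilTrace(samples=x, fs=trace.fs, blinks=list(trace.blinks),
                     onsets=trace.onsets.copy())
    return out, mask


def lowpass_filter(samples: np.ndarray, fs: float, cutoff_hz: float = 4.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, samples)


def preprocess_and_epoch(trace: PupilTrace, mask: np.ndarray | None = None,
                         cutoff_hz: float = 4.0,
                         window_ms: tuple[float, float] = (-500.0, 3000.0),
                         reject_threshold: float = REJECT_THRESHOLD
                         ) -> list[PupilEpoch]:
    """Low-pass the continuous trace and cut event-locked epochs.

    ``mask`` is the interpolation mask from :func:`interpolate_blinks`; the
    fraction of interpolated samples per epoch drives the rejection rule
    (fraction > ``reject_threshold``  <=>  rejected).  Events whose window
    extends past the trace edges are dropped with a warning.
    """
    filtered = lowpass_filter(trace.samples, trace.fs, cutoff_hz)
    if mask is None:
        mask = np.zeros(filtered.size, dtype=bool)
    ms_per_sample = 1000.0 / trace.fs
    i_lo = int(round(window_ms[0] / ms_per_sample))
    i_hi = int(round(window_ms[1] / ms_per_sample))
    times = np.arange(i_lo, i_hi) * ms_per_sample
    epochs = []
    for onset in trace.onsets:
        a, b = onset + i_lo, onset + i_hi
        if a < 0 or b > filtered.size:
            warnings.warn(f"onset {onset}: epoch window outside trace; dropped")
            continue
        seg = filtered[a:b].copy()
        frac = float(mask[a:b].mean())
        ep = PupilEpoch(samples=seg, times_ms=times.copy(),
                        interpolated_fraction=frac, state="raw",
                        rejected=frac > reject_threshold,
                        onset_index=int(onset))
        ep.baseline_value = float(seg[ep.baseline_mask()].mean())
        epochs.append(ep)
    return epochs


def divisive_baseline(epoch: PupilEpoch) -> PupilEpoch:
    """Divide every sample by the mean pupil size over -200..0 ms.

    Turns the epoch into a relative change signal whose baseline-window mean
    is exactly 1.  A non-positive baseline mean raises.
    """
    if epoch.state != "raw":
        raise ValueError(f"divisive baseline expects a raw epoch, got {epoch.state!r}")
    base = float(epoch.samples[epoch.baseline_mask()].mean())
    if not np.isfinite(base) or base <= 0:
        raise ValueError(f"non-positive baseline mean {base}; epoch unusable")
    return replace(epoch, samples=epoch.samples / base, baseline_value=base,
                   state="divisive_baselined")


def pdr_derivative(epoch: PupilEpoch, subtract_baseline: bool = False,
                   smooth_samples: int = 200) -> PupilEpoch:
    """Pupil dilation response derivative (PDR').

    First difference of the raw (unbaselined) epoch, one value per sample
    pair, then a centered ``smooth_samples``-point moving mean (shrinking at
    the epoch edges so the length is preserved).  With ``subtract_baseline``
    the mean of the smoothed derivative over -200..0 ms is subtracted, which
    removes a linear pre-stimulus trend from the underlying trace.
    """
    if epoch.state != "raw":
        raise ValueError(f"PDR' expects a raw epoch, got {epoch.state!r}")
    d = np.diff(epoch.samples)
    if smooth_samples > 1:
        d = (pd.Series(d).rolling(smooth_samples, center=True, min_periods=1)
             .mean().to_numpy())
    times = epoch.times_ms[:-1]
    out = replace(epoch, samples=d, times_ms=times, state="derivative")
    if subtract_baseline:
        base = float(d[out.baseline_mask()].mean())
        out = replace(out, samples=d - base, baseline_value=base)
    return out


def epochs_to_frame(epochs: list[PupilEpoch]) -> pd.DataFrame:
    """Long-format table (epoch, time_ms, value, rejected) for CSV export."""
    frames = []
    for k, ep in enumerate(epochs):
        frames.append(pd.DataFrame({
            "epoch": k, "time_ms": ep.times_ms, "value": ep.samples,
            "rejected": ep.rejected,
            "interpolated_fraction": ep.interpolated_fraction}))
    return pd.concat(frames, ignore_index=True)
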