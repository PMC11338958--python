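"""Behavioral summaries for near-threshold detection experiments.

Operates on tidy trial tables (one row per trial) with columns

    participant_id, condition ('signal' | 'absent' | 'am_noise'),
    rating (1..6 for the rating task; 0/1 for binary detection),
    run, trial_index (chronological within participant), baseline_pupil, valid

A trial counts as "detected" when its rating exceeds the dichotomization cut
(ratings 4-6 with the default cut of 3; for binary data use cut=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdt_core import clip_rate, criterion_from_rates, d_prime

REQUIRED_COLUMNS = ("participant_id", "condition", "rating")


def _validate(trials: pd.DataFrame, need=REQUIRED_COLUMNS) -> None:
    missing = [c for c in need if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")


@dataclass(frozen=True)
class BehavioralSummary:
    """Hit/false-alarm rates with the derived criterion and sensitivity.

    Rates are the raw observed proportions; ``criterion_c`` and ``d_prime``
    are computed on 1/(2N)-clipped rates so they stay finite.
    """

    hit_rate: float
    fa_rate: float
    criterion_c: float
    d_prime: float
    n_signal: int
    n_absent: int


def dichotomize_ratings(trials: pd.DataFrame, cut: int = 3) -> BehavioralSummary:
    """Collapse ratings into hits (rating > cut) vs misses and summarize.

    Returns the hit rate over signal trials, the false-alarm rate over
    signal-absent trials, criterion c = -(z(H)+z(FA))/2 and d' = z(H)-z(FA).
    """
    _validate(trials)
    if not (0 <= cut <= 5):
        raise ValueError("cut must lie in 0..5")
    signal = trials[trials["condition"] == "signal"]
    absent = trials[trials["condition"] == "absent"]
    if signal.empty or absent.empty:
        raise ValueError("need at least one signal and one signal-absent trial")
    h = float((signal["rating"] > cut).mean())
    fa = float((absent["rating"] > cut).mean())
    return BehavioralSummary(
        hit_rate=h, fa_rate=fa,
        criterion_c=criterion_from_rates(h, fa, len(signal), len(absent)),
        d_prime=d_prime(h, fa, len(signal), len(absent)),
        n_signal=len(signal), n_absent=len(absent))


def summaries_by_participant(trials: pd.DataFrame, cut: int = 3) -> pd.DataFrame:
    """Per-participant :func:`dichotomize_ratings`, one row each."""
    rows = []
    for pid, sub in trials.groupby("participant_id"):
        s = dichotomize_ratings(sub, cut=cut)
        rows.append({"participant_id": pid, "hit_rate": s.hit_rate,
                     "fa_rate": s.fa_rate, "criterion_c": s.criterion_c,
                     "d_prime": s.d_prime})
    return pd.DataFrame(rows)


def predictive_values(trials: pd.DataFrame) -> pd.DataFrame:
    """Positive and negative predictive values per rating.

    Per rating r the per-rating response rates are counts divided by the
    total signal-present (HR_r, MR_r) or signal-absent (FAR_r, CRR_r) trial
    counts; then

        PPV_r = HR_r / (HR_r + FAR_r)    (threshold assumed below rating 1)
        NPV_r = CRR_r / (CRR_r + MR_r)   (threshold assumed above rating 6)

    so each value is invariant to any dichotomization threshold on its side
    of the rating.  Ratings whose denominator is zero are NaN (undefined),
    never silently zero.
    """
    _validate(trials)
    signal = trials[trials["condition"] == "signal"]
    absent = trials[trials["condition"] == "absent"]
    if signal.empty or absent.empty:
        raise ValueError("need signal and signal-absent trials")
    ratings = np.arange(1, 7)
    hr = np.array([(signal["rating"] == r).mean() for r in ratings])
    far = np.array([(absent["rating"] == r).mean() for r in ratings])
    # a response with rating r is a "present" call for PPV and an "absent"
    # call for NPV, so MR/CRR reuse the same per-rating rates
    mr, crr = hr, far
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(hr + far > 0, hr / (hr + far), np.nan)
        npv = np.where(crr + mr > 0, crr / (crr + mr), np.nan)
    return pd.DataFrame({"rating": ratings, "HR": hr, "FAR": far,
                         "CRR": crr, "MR": mr, "PPV": ppv, "NPV": npv})


def _equal_count_bins(n: int, n_bins: int) -> np.ndarray:
    """Bin sizes for n items in n_bins bins; remainder goes to the lowest bins."""
    base, rem = divmod(n, n_bins)
    if base == 0:
        raise ValueError(f"cannot split {n} trials into {n_bins} bins")
    return np.array([base + 1] * rem + [base] * (n_bins - rem))


def pupil_quintile_rates(trials: pd.DataFrame, cut: int = 3,
                         n_bins: int = 5) -> tuple[np.ndarray, pd.DataFrame]:
    """Detection rate as a function of pre-stimulus baseline pupil size.

    Per participant, signal trials are stably sorted by baseline pupil
    (chronological index as tie-breaker) and split into ``n_bins``
    equal-count bins (remainder trials go to the lowest bins); the detection
    rate (rating > cut) is computed per bin and then averaged across
    participants.  Returns (group mean per bin, per-participant table).
    """
    _validate(trials, REQUIRED_COLUMNS + ("baseline_pupil",))
    rows = []
    for pid, sub in trials[trials["condition"] == "signal"].groupby("participant_id"):
        sub = sub.reset_index(drop=True)
        if len(sub) < n_bins:
            raise ValueError(f"participant {pid}: fewer trials than bins")
        tiebreak = sub["trial_index"].to_numpy() if "trial_index" in sub else np.arange(len(sub))
        order = np.lexsort((tiebreak, sub["baseline_pupil"].to_numpy()))
        detected = (sub["rating"].to_numpy() > cut)[order]
        sizes = _equal_count_bins(len(sub), n_bins)
        splits = np.split(detected, np.cumsum(sizes)[:-1])
        for b, part in enumerate(splits):
            rows.append({"participant_id": pid, "bin": b + 1,
                         "n_trials": part.size, "rate": float(part.mean())})
    table = pd.DataFrame(rows)
    group = table.groupby("bin")["rate"].mean().to_numpy()
    return group, table


def chronological_split_rates(trials: pd.DataFrame, n_parts: int = 5,
                              cut: int = 3) -> tuple[np.ndarray, pd.DataFrame]:
    """Detection rate over consecutive, equally large parts of each session.

    Trials stay in chronological order (``trial_index``); signal trials are
    split into ``n_parts`` consecutive parts per participant, detection rates
    are computed per part and then averaged across participants.
    """
    _validate(trials, REQUIRED_COLUMNS + ("trial_index",))
    rows = []
    for pid, sub in trials[trials["condition"] == "signal"].groupby("participant_id"):
        sub = sub.sort_values("trial_index").reset_index(drop=True)
        if n_parts > len(sub):
            raise ValueError(f"participant {pid}: n_parts exceeds trial count")
        detected = (sub["rating"].to_numpy() > cut)
        sizes = _equal_count_bins(len(sub), n_parts)
        splits = np.split(detected, np.cumsum(sizes)[:-1])
        for b, part in enumerate(splits):
            rows.append({"participant_id": pid, "part": b + 1,
                         "n_trials": part.size, "rate": float(part.mean())})
    table = pd.DataFrame(rows)
    group = table.groupby("part")["rate"].mean().to_numpy()
    return group, table


def rating_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x class counts of each rating (wide, n_r1..n_r6)."""
    _validate(trials)
    rows = []
    for (pid, cond), sub in trials.groupby(["participant_id", "condition"]):
        if cond not in ("signal", "absent"):
            continue
        counts = [(sub["rating"] == r).sum() for r in range(1, 7)]
        rows.append({"participant_id": pid,
                     "class": "signal" if cond == "signal" else "noise",
                     **{f"n_r{r}": int(c) for r, c in zip(range(1, 7), counts)}})
    return pd.DataFrame(rows)
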