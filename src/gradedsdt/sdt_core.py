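"""Unequal-variance Gaussian signal detection machinery for rating-scale data.

The model assumes a latent evidence axis on which signal-absent ("noise")
trials draw from N(mu_noise, sigma_noise^2) and signal-present trials from
N(mu_signal, sigma_signal^2), with the noise distribution fixed at N(0, 1) by
convention.  An observer rating on a K-point scale corresponds to K-1 ordered
decision criteria partitioning the axis into K bins; rating k is reported when
the evidence falls in bin k.

This module provides

* criterion and d' computation from hit/false-alarm rates,
* the rating-scale ROC and its z-transformed slope, which estimates
  sigma_noise / sigma_signal,
* grand-average estimation of (mu_signal, sigma_signal) by matching the
  criteria implied by the noise-side and signal-side cumulative rating
  probabilities,
* per-participant criterion estimation given a fitted model,
* closed-form truncated-Gaussian mean amplitudes per rating bin (the model's
  prediction for any neural readout that tracks the evidence variable),
* the shift-and-scale normalization used before comparing predicted and
  measured amplitude profiles, and a coefficient of determination.

All probability clipping follows the 1/(2N) rule, with N the number of trials
backing a rate, so that z-transforms stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

logger = logging.getLogger(__name__)

N_RATINGS = 6
#: search bounds for individual decision criteria, in noise-SD units
CRITERION_BOUNDS = (-6.0, 6.0)
#: probability mass below which a rating bin is treated as degenerate
MASS_FLOOR = 1e-12


class UnderdeterminedError(ValueError):
    """Raised when an estimator has too few usable data points."""


class NormalizationError(ValueError):
    """Raised when an amplitude-profile normalization is ill-defined."""


class FitError(RuntimeError):
    """Raised when a model fit fails to locate a usable optimum."""


# ---------------------------------------------------------------------------
# rate utilities
# ---------------------------------------------------------------------------

def clip_rate(rate, n_trials: int | None = None):
    """Clip a proportion into the open unit interval.

    Uses the standard ``1/(2N)`` correction when a backing trial count is
    available, otherwise a fixed ``1e-6`` floor.  Rates outside [0, 1] raise.
    Clipping is logged, never silent.
    """
    arr = np.asarray(rate, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError(f"rate outside [0, 1]: {rate!r}")
    if n_trials is not None and n_trials > 0:
        lo = 1.0 / (2.0 * n_trials)
    else:
        lo = 1e-6
    clipped = np.clip(arr, lo, 1.0 - lo)
    if np.any(clipped != arr):
        logger.warning("rate(s) clipped into (%g, %g)", lo, 1.0 - lo)
    return float(clipped) if np.isscalar(rate) or arr.ndim == 0 else clipped


def criterion_from_rates(hit_rate: float, fa_rate: float,
                         n_signal: int | None = None,
                         n_noise: int | None = None) -> float:
    """Decision criterion c = -(z(H) + z(FA)) / 2.

    ``c`` is in noise-SD units; positive values mean a conservative observer.
    Rates exactly 0 or 1 are clipped (see :func:`clip_rate`) with a warning.
    """
    h = clip_rate(hit_rate, n_signal)
    f = clip_rate(fa_rate, n_noise)
    return float(-(norm.ppf(h) + norm.ppf(f)) / 2.0)


def d_prime(hit_rate: float, fa_rate: float,
            n_signal: int | None = None, n_noise: int | None = None) -> float:
    """Sensitivity d' = z(H) - z(FA), after clipping."""
    h = clip_rate(hit_rate, n_signal)
    f = clip_rate(fa_rate, n_noise)
    return float(norm.ppf(h) - norm.ppf(f))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianSdtModel:
    """Unequal-variance Gaussian evidence model.

    The noise distribution is N(mu_noise, sigma_noise^2), fixed at N(0, 1) by
    convention; the signal distribution is N(mu_signal, sigma_signal^2).
    """

    mu_signal: float
    sigma_signal: float
    mu_noise: float = 0.0
    sigma_noise: float = 1.0

    def __post_init__(self):
        if not (self.sigma_noise > 0 and self.sigma_signal > 0):
            raise ValueError("standard deviations must be positive")

    @property
    def delta_mu(self) -> float:
        return self.mu_signal - self.mu_noise

    @property
    def delta_sigma(self) -> float:
        return self.sigma_signal - self.sigma_noise

    @property
    def delta_ratio(self) -> float:
        """delta_mu / delta_sigma (infinite for an equal-variance model)."""
        if self.delta_sigma == 0.0:
            return float("inf")
        return self.delta_mu / self.delta_sigma

    def component(self, class_label: str) -> tuple[float, float]:
        """(mu, sigma) of the requested class distribution."""
        if class_label == "signal":
            return self.mu_signal, self.sigma_signal
        if class_label == "noise":
            return self.mu_noise, self.sigma_noise
        raise ValueError(f"unknown class label {class_label!r}")

    def density(self, x, class_label: str = "signal"):
        mu, sigma = self.component(class_label)
        return norm.pdf(np.asarray(x, dtype=float), loc=mu, scale=sigma)


@dataclass(frozen=True)
class CriterionSet:
    """Ordered decision criteria c_1 < ... < c_{K-1} on the evidence axis.

    The implicit outer boundaries are c_0 = -inf and c_K = +inf, so K-1
    criteria define K rating bins.
    """

    criteria: np.ndarray
    repaired: bool = False
    at_bounds: bool = False

    def __post_init__(self):
        arr = np.atleast_1d(np.asarray(self.criteria, dtype=float))
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("criteria must be a non-empty 1-d vector")
        if np.any(~np.isfinite(arr)):
            raise ValueError("criteria must be finite")
        if np.any(np.diff(arr) <= 0):
            raise ValueError(f"criteria must be strictly increasing: {arr}")
        object.__setattr__(self, "criteria", arr)

    @property
    def n_ratings(self) -> int:
        return self.criteria.size + 1

    @property
    def edges(self) -> np.ndarray:
        """Bin edges including the infinite outer boundaries."""
        return np.concatenate(([-np.inf], self.criteria, [np.inf]))


@dataclass(frozen=True)
class RatingProbabilities:
    """Per-class probabilities of each rating (sum to one)."""

    class_label: str
    probs: np.ndarray
    n_trials: int = 0

    def __post_init__(self):
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 1:
            raise ValueError("probs must be a 1-d vector")
        if np.any(arr < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {arr.sum()}")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        object.__setattr__(self, "probs", arr)

    @classmethod
    def from_counts(cls, class_label: str, counts) -> "RatingProbabilities":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("counts must contain at least one trial")
        return cls(class_label, counts / total, n_trials=int(round(total)))

    def upper_tail(self) -> np.ndarray:
        """P(rating > k) for k = 1 .. K-1 (the cumulative response rates)."""
        return 1.0 - np.cumsum(self.probs)[:-1]

    @classmethod
    def analytic(cls, class_label: str, model: GaussianSdtModel,
                 criteria: CriterionSet) -> "RatingProbabilities":
        """Exact rating probabilities implied by a model and criteria."""
        mu, sigma = model.component(class_label)
        cdf = norm.cdf(criteria.edges, loc=mu, scale=sigma)
        return cls(class_label, np.diff(cdf), n_trials=0)


@dataclass(frozen=True)
class RocPoints:
    """Cumulative (hit, false-alarm) pairs of the rating-scale ROC.

    Point k pools ratings above k as "present" responses, so rates are
    non-increasing in k (criteria get more conservative).
    """

    hit_rates: np.ndarray
    fa_rates: np.ndarray
    n_signal: int = 0
    n_noise: int = 0

    def __post_init__(self):
        h = np.asarray(self.hit_rates, dtype=float)
        f = np.asarray(self.fa_rates, dtype=float)
        if h.shape != f.shape or h.ndim != 1:
            raise ValueError("hit and false-alarm rates must be matching 1-d vectors")
        for arr in (h, f):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("rates must lie in [0, 1]")
            if np.any(np.diff(arr) > 1e-9):
                raise ValueError("cumulative rates must be non-increasing")
        object.__setattr__(self, "hit_rates", h)
        object.__setattr__(self, "fa_rates", f)


@dataclass(frozen=True)
class AmplitudeProfile:
    """Mean amplitude per rating for one class, with normalization state."""

    class_label: str
    values: np.ndarray
    state: str = "raw"  # raw | shifted | shifted_and_scaled
    shift: float = 0.0
    scale: float = 1.0
    degenerate: np.ndarray = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.degenerate is None:
            object.__setattr__(self, "degenerate",
                               np.zeros(vals.size, dtype=bool))
        else:
            object.__setattr__(self, "degenerate",
                               np.asarray(self.degenerate, dtype=bool))
        if self.state not in ("raw", "shifted", "shifted_and_scaled"):
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class FitReport:
    """Container for one fitted model and its fit to measured amplitudes."""

    model_name: str
    parameters: dict
    criteria: dict
    predicted: dict
    measured: dict | None = None
    r_squared: float | None = None

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, AmplitudeProfile):
                return {"class": obj.class_label, "state": obj.state,
                        "values": obj.values.tolist(),
                        "shift": obj.shift, "scale": obj.scale}
            if isinstance(obj, CriterionSet):
                return obj.criteria.tolist()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return _clean({"model": self.model_name, "parameters": self.parameters,
                       "criteria": self.criteria, "predicted": self.predicted,
                       "measured": self.measured, "r_squared": self.r_squared})


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def cumulative_response_rates(signal: RatingProbabilities,
                              noise: RatingProbabilities) -> RocPoints:
    """Rating-scale ROC points from per-class rating probabilities.

    Point k has hit rate sum_{i>k} p_signal,i and false-alarm rate
    sum_{i>k} p_noise,i, i.e. criterion 1 is the most liberal (everything
    above rating 1 counts as "present").
    """
    if signal.probs.size != noise.probs.size:
        raise ValueError("signal and noise probability vectors differ in length")
    return RocPoints(hit_rates=signal.upper_tail(),
                     fa_rates=noise.upper_tail(),
                     n_signal=signal.n_trials, n_noise=noise.n_trials)


def solve_criterion(p_right: float, mu: float = 0.0, sigma: float = 1.0) -> float:
    """Criterion c with upper-tail probability ``p_right`` under N(mu, sigma^2).

    Closed form c = mu + sigma * Phi^-1(1 - p_right).  ``p_right`` must be
    strictly inside (0, 1); the caller is responsible for clipping.
    """
    if not (0.0 < p_right < 1.0):
        raise ValueError(f"tail probability {p_right} yields an infinite criterion")
    return float(mu + sigma * norm.isf(p_right))


def _york_slope(x, y, var_x, var_y, b0: float) -> float:
    """Straight-line slope with errors in both coordinates (York's method).

    Iteratively reweighted least squares with point weights
    1 / (var_y + b^2 var_x); reduces both the variance and the attenuation
    bias that plain OLS suffers from noisy extreme ROC points.
    """
    b = b0
    for _ in range(100):
        w = 1.0 / (var_y + b * b * var_x)
        xbar = (w * x).sum() / w.sum()
        ybar = (w * y).sum() / w.sum()
        u, v = x - xbar, y - ybar
        beta = w * (u * var_y * w + b * v * var_x * w)
        denom = (w * beta * u).sum()
        if abs(denom) < 1e-300:
            break
        b_new = (w * beta * v).sum() / denom
        if abs(b_new - b) < 1e-12:
            return float(b_new)
        b = b_new
    return float(b)


def estimate_sigma_ratio(roc: RocPoints) -> float:
    """sigma_noise / sigma_signal as the slope of the z-transformed ROC.

    Under the Gaussian model z(H) = delta_mu/sigma_signal +
    z(FA) * sigma_noise/sigma_signal, so the z-ROC slope is the SD ratio.
    When the ROC carries backing trial counts the line is fitted by weighted
    least squares with errors in both coordinates (binomial delta-method
    variances, York's iteration), which keeps the noisy extreme points from
    dominating; without counts (exact probabilities) plain OLS is used.
    """
    h = clip_rate(roc.hit_rates, roc.n_signal or None)
    f = clip_rate(roc.fa_rates, roc.n_noise or None)
    zh, zf = norm.ppf(h), norm.ppf(f)
    if np.any(~np.isfinite(zh)) or np.any(~np.isfinite(zf)):
        raise ValueError("non-finite z-scores after clipping")
    # collapse duplicate points so a degenerate ROC is detected
    pts = np.unique(np.column_stack([zf, zh]), axis=0)
    if pts.shape[0] < 2 or np.ptp(pts[:, 0]) < 1e-12:
        raise UnderdeterminedError("need >= 2 distinct ROC points to fit the z-ROC")
    slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
    if roc.n_signal > 0 and roc.n_noise > 0:
        var_zh = h * (1 - h) / roc.n_signal / norm.pdf(zh) ** 2
        var_zf = f * (1 - f) / roc.n_noise / norm.pdf(zf) ** 2
        slope = _york_slope(zf, zh, var_zf, var_zh, slope)
    if slope <= 0:
        raise FitError(f"non-positive z-ROC slope {slope}")
    return float(slope)


def _noise_criteria(fa_tail: np.ndarray, model: GaussianSdtModel) -> np.ndarray:
    mu, sigma = model.component("noise")
    return mu + sigma * norm.isf(fa_tail)


def fit_signal_distribution(grand_signal: RatingProbabilities,
                            grand_noise: RatingProbabilities,
                            mu_bounds: tuple[float, float] = (0.0, 5.0),
                            sigma_signal: float | None = None,
                            tol: float = 1e-6) -> GaussianSdtModel:
    """Fit (mu_signal, sigma_signal) to grand-average rating probabilities.

    With mu_noise = 0 and sigma_noise = 1 fixed, sigma_signal comes from the
    z-ROC slope (unless supplied) and mu_signal minimizes the summed absolute
    differences between the criteria implied by the noise-side and the
    signal-side cumulative probabilities — on noiseless data the two criterion
    sets coincide at the generating mu_signal.

    ``sigma_signal`` may be passed explicitly to force e.g. an equal-variance
    fit; ``mu_bounds`` bounds the mean search (grid prescan + Brent refine).
    """
    roc = cumulative_response_rates(grand_signal, grand_noise)
    if sigma_signal is None:
        ratio = estimate_sigma_ratio(roc)
        sigma_signal = 1.0 / ratio
    fa = clip_rate(roc.fa_rates, grand_noise.n_trials or None)
    h = clip_rate(roc.hit_rates, grand_signal.n_trials or None)
    c_noise = norm.isf(fa)          # mu_noise = 0, sigma_noise = 1
    z_signal = norm.isf(h)

    def objective(mu):
        return float(np.abs(c_noise - (mu + sigma_signal * z_signal)).sum())

    lo, hi = mu_bounds
    grid = np.linspace(lo, hi, 201)
    vals = np.abs(c_noise[None, :] -
                  (grid[:, None] + sigma_signal * z_signal[None, :])).sum(axis=1)
    j = int(np.argmin(vals))
    step = grid[1] - grid[0]
    res = minimize_scalar(objective, bounds=(max(lo, grid[j] - step),
                                             min(hi, grid[j] + step)),
                          method="bounded", options={"xatol": tol})
    mu_signal = float(res.x)
    if min(mu_signal - lo, hi - mu_signal) < 10 * tol and objective(mu_signal) > 1e-6:
        raise FitError(
            f"mu_signal search hit bound {mu_signal:.4f} in {mu_bounds} "
            f"(objective {objective(mu_signal):.4g}); widen mu_bounds")
    return GaussianSdtModel(mu_signal=mu_signal, sigma_signal=float(sigma_signal))


def _pava_increasing(x: np.ndarray) -> np.ndarray:
    """Pool adjacent violators to make x non-decreasing (unit weights)."""
    x = x.astype(float).copy()
    n = x.size
    level = x.copy()
    weight = np.ones(n)
    idx = 0
    # simple stack-based PAVA
    levels, weights = [], []
    for i in range(n):
        levels.append(x[i]); weights.append(1.0)
        while len(levels) > 1 and levels[-2] > levels[-1]:
            w = weights[-1] + weights[-2]
            v = (levels[-1] * weights[-1] + levels[-2] * weights[-2]) / w
            levels = levels[:-2] + [v]
            weights = weights[:-2] + [w]
    out = np.concatenate([np.full(int(w), v) for v, w in zip(levels, weights)])
    return out


def fit_participant_criteria(signal: RatingProbabilities,
                             noise: RatingProbabilities,
                             model: GaussianSdtModel,
                             bounds: tuple[float, float] = CRITERION_BOUNDS,
                             signal_sf=None) -> CriterionSet:
    """Per-participant criteria given a fitted evidence model.

    Each c_i independently minimizes

        |P_noise(X > c_i) - p_FA,i| + |P_signal(X > c_i) - p_H,i|

    where p_FA,i / p_H,i are the observed cumulative rates.  Ties (within
    1e-10 of the optimum) break toward the noise-only solution.  If the five
    solutions are not strictly increasing they are repaired by isotonic
    pooling and flagged ``repaired=True``; solutions at the search bounds set
    ``at_bounds=True``.

    ``signal_sf`` may override the signal-class upper-tail function (e.g. a
    mixture tail); it must map an evidence value to P(X > c).
    """
    ph = signal.upper_tail()
    pfa = noise.upper_tail()
    mu_n, sd_n = model.component("noise")
    if signal_sf is None:
        mu_s, sd_s = model.component("signal")
        signal_sf = lambda c: norm.sf(c, loc=mu_s, scale=sd_s)
    lo, hi = bounds
    grid = np.linspace(lo, hi, 481)
    sf_noise_grid = norm.sf(grid, loc=mu_n, scale=sd_n)
    sf_signal_grid = signal_sf(grid)
    solutions = np.empty(ph.size)
    for i in range(ph.size):
        f = lambda c: (abs(norm.sf(c, loc=mu_n, scale=sd_n) - pfa[i])
                       + abs(signal_sf(c) - ph[i]))
        vals = np.abs(sf_noise_grid - pfa[i]) + np.abs(sf_signal_grid - ph[i])
        j = int(np.argmin(vals))
        res = minimize_scalar(f, bounds=(grid[max(j - 1, 0)],
                                         grid[min(j + 1, grid.size - 1)]),
                              method="bounded", options={"xatol": 1e-10})
        c_best, f_best = float(res.x), float(res.fun)
        # tie-break toward the noise-only solution
        p = float(np.clip(pfa[i], 1e-12, 1 - 1e-12))
        c_noise_only = float(np.clip(solve_criterion(p, mu_n, sd_n), lo, hi))
        if f(c_noise_only) <= f_best + 1e-10:
            c_best = c_noise_only
        solutions[i] = c_best
    at_bounds = bool(np.any((np.abs(solutions - lo) < 1e-6) |
                            (np.abs(solutions - hi) < 1e-6)))
    repaired = False
    if np.any(np.diff(solutions) <= 0):
        solutions = _pava_increasing(solutions)
        # break exact ties left by pooling with an epsilon ladder
        for k in range(1, solutions.size):
            if solutions[k] <= solutions[k - 1]:
                solutions[k] = solutions[k - 1] + 1e-8
        repaired = True
        logger.warning("criteria repaired to be strictly increasing")
    return CriterionSet(solutions, repaired=repaired, at_bounds=at_bounds)


def predicted_amplitudes(model: GaussianSdtModel, criteria: CriterionSet,
                         class_label: str = "signal") -> AmplitudeProfile:
    """Mean evidence per rating bin: the truncated-Gaussian conditional mean.

    For bin (c_{i-1}, c_i] the closed form is
    mu + sigma * (phi(a) - phi(b)) / (Phi(b) - Phi(a)) with a, b the
    standardized edges.  Bins with probability mass below ``MASS_FLOOR``
    return the (clipped) bin midpoint and are flagged degenerate.
    """
    mu, sigma = model.component(class_label)
    edges = criteria.edges
    a = (edges[:-1] - mu) / sigma
    b = (edges[1:] - mu) / sigma
    mass = norm.cdf(b) - norm.cdf(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = mu + sigma * (norm.pdf(a) - norm.pdf(b)) / mass
    degenerate = mass < MASS_FLOOR
    if np.any(degenerate):
        logger.warning("%d rating bin(s) carry ~zero mass; reporting midpoints",
                       int(degenerate.sum()))
        lo_edges = np.maximum(edges[:-1], mu - 8 * sigma)
        hi_edges = np.minimum(edges[1:], mu + 8 * sigma)
        values = np.where(degenerate, (lo_edges + hi_edges) / 2.0, values)
    return AmplitudeProfile(class_label=class_label, values=values,
                            state="raw", degenerate=degenerate)


def normalize_profiles(noise_profile: AmplitudeProfile,
                       signal_profile: AmplitudeProfile,
                       shift: float,
                       divisor: float | None = None
                       ) -> tuple[AmplitudeProfile, AmplitudeProfile]:
    """Shift-and-scale normalization of a (noise, signal) profile pair.

    ``shift`` is subtracted from every amplitude (the across-participant mean
    of the noise-class rating-1 amplitude, so that value maps to 0), then both
    profiles are divided by the post-shift signal-class rating-1 amplitude
    A_H1 (override with ``divisor``).
    """
    for p in (noise_profile, signal_profile):
        if p.state != "raw":
            raise NormalizationError(f"expected raw profiles, got {p.state!r}")
    if not np.isfinite(shift):
        raise NormalizationError("shift must be finite")
    shifted_noise = noise_profile.values - shift
    shifted_signal = signal_profile.values - shift
    if divisor is None:
        divisor = float(shifted_signal[0])
    if not np.isfinite(divisor) or divisor <= 0:
        raise NormalizationError(f"normalization divisor {divisor} must be positive")
    mk = lambda prof, vals: replace(prof, values=vals / divisor,
                                    state="shifted_and_scaled",
                                    shift=shift, scale=divisor)
    return mk(noise_profile, shifted_noise), mk(signal_profile, shifted_signal)


def _as_values(profiles) -> np.ndarray:
    if isinstance(profiles, AmplitudeProfile):
        return profiles.values
    if isinstance(profiles, (list, tuple)) and profiles and \
            isinstance(profiles[0], AmplitudeProfile):
        states = {p.state for p in profiles}
        if len(states) > 1:
            raise ValueError(f"mixed normalization states {states}")
        return np.concatenate([p.values for p in profiles])
    return np.asarray(profiles, dtype=float)


def goodness_of_fit(predicted, measured) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot.

    Accepts arrays, single profiles, or sequences of profiles (concatenated
    rating-wise).  Can be negative for models worse than the mean; raises on
    zero total variance.
    """
    p = _as_values(predicted)
    m = _as_values(measured)
    if p.shape != m.shape:
        raise ValueError("predicted and measured must have the same length")
    if isinstance(predicted, AmplitudeProfile) and isinstance(measured, AmplitudeProfile):
        if predicted.state != measured.state:
            raise ValueError("profiles must share a normalization state")
    ss_tot = float(((m - m.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("zero total variance: R^2 undefined")
    ss_res = float(((m - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot
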