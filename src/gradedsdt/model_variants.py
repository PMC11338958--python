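"""Competitor evidence models: bimodal ("bifurcation") and threshold accounts.

The bifurcation account replaces the unimodal Gaussian signal distribution by
a two-component mixture: a fraction ``beta`` of signal trials reaches an upper
("detected") mode while the remainder stays in a lower mode, all components
sharing the noise standard deviation.  ``beta`` is set externally from the
dichotomized detection rate.  The threshold account keeps the Gaussian model
but assumes sub-threshold ratings evoke no perception-related response, so
their predicted amplitudes are zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm, pearsonr

from .sdt_core import (AmplitudeProfile, CriterionSet, FitError,
                       GaussianSdtModel, RatingProbabilities, clip_rate,
                       cumulative_response_rates, MASS_FLOOR)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BimodalSignalModel:
    """Two-mode signal distribution with a noise-like lower mode.

    density(x) = (1-beta) N(x; mu_low, sigma) + beta N(x; mu_high, sigma);
    the noise distribution is N(mu_low, sigma) with sigma shared by all
    components (sigma = 1 by convention).
    """

    beta: float
    mu_high: float
    mu_low: float = 0.0
    sigma_common: float = 1.0
    flags: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if np.isfinite(self.mu_high) and self.mu_low > self.mu_high:
            raise ValueError("mu_low must not exceed mu_high")
        if not self.sigma_common > 0:
            raise ValueError("sigma_common must be positive")

    def density(self, x):
        x = np.asarray(x, dtype=float)
        return ((1.0 - self.beta) * norm.pdf(x, self.mu_low, self.sigma_common)
                + self.beta * norm.pdf(x, self.mu_high, self.sigma_common))

    def sf(self, c):
        """Upper-tail probability P(X > c) of the mixture."""
        c = np.asarray(c, dtype=float)
        return ((1.0 - self.beta) * norm.sf(c, self.mu_low, self.sigma_common)
                + self.beta * norm.sf(c, self.mu_high, self.sigma_common))

    def solve_criterion(self, p_right: float, tol: float = 1e-8) -> float:
        """Invert the mixture tail numerically (no closed-form quantile).

        The tail is strictly decreasing in c, so bisection has a unique root.
        """
        if not (0.0 < p_right < 1.0):
            raise ValueError("tail probability must be strictly inside (0, 1)")
        lo = self.mu_low - 10 * self.sigma_common
        hi = self.mu_high + 10 * self.sigma_common
        return float(brentq(lambda c: self.sf(c) - p_right, lo, hi, xtol=tol))


def beta_from_hit_rate(hit_rate: float) -> float:
    """Mixture weight of the upper mode from the dichotomized detection rate.

    The fraction of signal trials reaching the "detected" mode is taken to be
    the group-mean dichotomized hit rate, rounded to two decimals.
    """
    if not (0.0 <= hit_rate <= 1.0):
        raise ValueError("hit rate must lie in [0, 1]")
    return round(float(hit_rate), 2)


def bimodal_density(x, model: BimodalSignalModel):
    """Mixture density; thin functional alias of ``model.density``."""
    return model.density(x)


def fit_bimodal_model(grand_signal: RatingProbabilities,
                      grand_noise: RatingProbabilities,
                      beta: float,
                      mu_bounds: tuple[float, float] = (0.0, 6.0),
                      tol: float = 1e-6) -> BimodalSignalModel:
    """Fit the upper-mode location to grand-average rating probabilities.

    The lower mode is pinned to the noise mean (0) and sigma_common to 1;
    only ``mu_high`` is searched, by the same criterion-consistency objective
    as the unimodal fit but with the mixture tail inverted numerically.
    ``beta`` comes from the dichotomized detection rate and is not fitted.
    A beta of 0 makes the signal distribution identical to noise; the fit is
    returned flagged ``unidentifiable`` with mu_high = mu_low.
    """
    if beta == 0.0:
        logger.warning("beta = 0: signal distribution degenerates to noise")
        return BimodalSignalModel(beta=0.0, mu_high=0.0,
                                  flags=("unidentifiable",))
    roc = cumulative_response_rates(grand_signal, grand_noise)
    fa = clip_rate(roc.fa_rates, grand_noise.n_trials or None)
    h = clip_rate(roc.hit_rates, grand_signal.n_trials or None)
    c_noise = norm.isf(fa)

    def objective(mu_high):
        m = BimodalSignalModel(beta=beta, mu_high=float(mu_high))
        c_signal = np.array([m.solve_criterion(p) for p in h])
        return float(np.abs(c_noise - c_signal).sum())

    lo, hi = mu_bounds
    grid = np.linspace(lo, hi, 61)
    vals = [objective(m) for m in grid]
    j = int(np.argmin(vals))
    step = grid[1] - grid[0]
    res = minimize_scalar(objective, bounds=(max(lo, grid[j] - step),
                                             min(hi, grid[j] + step)),
                          method="bounded", options={"xatol": tol})
    mu_high = float(res.x)
    if min(mu_high - lo, hi - mu_high) < 10 * tol and objective(mu_high) > 1e-6:
        raise FitError(f"mu_high search hit bound {mu_high:.4f} in {mu_bounds}")
    return BimodalSignalModel(beta=beta, mu_high=mu_high)


def bimodal_predicted_amplitudes(model: BimodalSignalModel,
                                 criteria: CriterionSet) -> AmplitudeProfile:
    """Mean mixture evidence per rating bin (signal class).

    Per component k the partial first moment over (lo, hi] is
    mu_k * mass_k + sigma * (phi(a_k) - phi(b_k)); the bin mean weights these
    by the mixture weights.  Zero-mass bins return the clipped midpoint,
    flagged degenerate.
    """
    edges = criteria.edges
    sigma = model.sigma_common
    weights = (1.0 - model.beta, model.beta)
    mus = (model.mu_low, model.mu_high)
    num = np.zeros(edges.size - 1)
    den = np.zeros(edges.size - 1)
    for w, mu in zip(weights, mus):
        a = (edges[:-1] - mu) / sigma
        b = (edges[1:] - mu) / sigma
        mass = norm.cdf(b) - norm.cdf(a)
        num += w * (mu * mass + sigma * (norm.pdf(a) - norm.pdf(b)))
        den += w * mass
    degenerate = den < MASS_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / den
    if np.any(degenerate):
        logger.warning("%d zero-mass bin(s) in bimodal prediction",
                       int(degenerate.sum()))
        lo_e = np.maximum(edges[:-1], model.mu_low - 8 * sigma)
        hi_e = np.minimum(edges[1:], model.mu_high + 8 * sigma)
        values = np.where(degenerate, (lo_e + hi_e) / 2.0, values)
    return AmplitudeProfile(class_label="signal", values=values, state="raw",
                            degenerate=degenerate)


@dataclass(frozen=True)
class ThresholdModel:
    """Gaussian evidence model plus a hard perceptual threshold.

    Ratings at or below ``threshold_rating`` are assumed sub-threshold and
    evoke no perception-related response; the default places the threshold
    between ratings 3 and 4.
    """

    base: GaussianSdtModel
    threshold_rating: int = 3

    def __post_init__(self):
        if not (0 <= self.threshold_rating <= 6):
            raise ValueError("threshold_rating must lie in 0..6")


def threshold_amplitudes(profile: AmplitudeProfile,
                         model: ThresholdModel) -> AmplitudeProfile:
    """Zero the amplitudes of sub-threshold ratings in a normalized profile."""
    if profile.state == "raw":
        raise ValueError("threshold model applies to normalized profiles only")
    values = profile.values.copy()
    values[:model.threshold_rating] = 0.0
    return replace(profile, values=values)


def distribution_similarity(density_a, density_b, grid) -> float:
    """Pearson correlation of two evidence densities on a common grid.

    ``density_a``/``density_b`` may be callables or objects with a
    ``density`` method (e.g. :class:`BimodalSignalModel`).  Raises when a
    density is numerically constant on the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 10:
        raise ValueError("grid must contain at least 10 points")

    def _eval(d):
        f = d.density if hasattr(d, "density") else d
        return np.asarray(f(grid), dtype=float)

    ya, yb = _eval(density_a), _eval(density_b)
    if ya.std() < 1e-15 or yb.std() < 1e-15:
        raise ValueError("density constant on grid: correlation undefined")
    return float(pearsonr(ya, yb).statistic)
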