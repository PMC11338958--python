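"""Group-level waveform statistics: window means, temporal cluster
permutation tests, polynomial contrasts, and repeated-measures ANOVA.

The cluster test is the one-sample (sign-flip) variant appropriate for
paired condition-vs-reference or condition-vs-zero designs: pointwise paired
t values inside an analysis window, contiguous supra-threshold runs scored by
summed t, and a family-wise null distribution of maximum cluster masses from
random within-participant sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

#: canonical analysis windows (ms) for the three readouts
WINDOWS_MS = {"AC": (100.0, 400.0), "RSC_PCC": (300.0, 800.0),
              "PDR": (500.0, 1000.0)}


@dataclass
class WaveformSet:
    """Participants x time matrix on a common time axis (ms)."""

    data: np.ndarray
    times_ms: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.shape[1] != self.times_ms.size:
            raise ValueError("data columns must match the time axis")

    def window_slice(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        mask = (self.times_ms >= lo) & (self.times_ms <= hi)
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        return mask


@dataclass
class ClusterResult:
    """Clusters as (start_ms, end_ms, mass, p_value) plus test metadata."""

    clusters: list
    n_permutations: int
    cluster_alpha: float
    times_ms: np.ndarray = None

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c[3] < 0.05]


@dataclass
class ContrastResult:
    """Linear and quadratic orthogonal-polynomial contrast F tests."""

    linear_f: float
    linear_p: float
    quadratic_f: float
    quadratic_p: float
    df: tuple
    bin_means: np.ndarray = None


def window_mean(waveforms: WaveformSet,
                window_ms: tuple[float, float]) -> np.ndarray:
    """Per-participant mean amplitude inside the analysis window."""
    mask = waveforms.window_slice(window_ms)
    return waveforms.data[:, mask].mean(axis=1)


def _t_from_signflips(x: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t for every sign-flip pattern, vectorized.

    Sign flips leave per-participant squared values unchanged, so only the
    flipped sums vary:  t = (M/n) / sqrt((SS - M^2/n) / (n(n-1))) with
    M = flips @ x and SS the fixed column sums of squares.
    """
    n = x.shape[0]
    m = flips @ x                       # (n_perm, T) flipped sums
    ss = (x ** 2).sum(axis=0)           # (T,)
    var = (ss[None, :] - m ** 2 / n) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m / n) / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _max_cluster_mass_rows(tmat: np.ndarray, thr: float) -> np.ndarray:
    """Per-row maximum |summed t| over contiguous supra-threshold runs.

    Positive (t > thr) and negative (t < -thr) runs are scored separately and
    pooled by absolute mass.  Vectorized across rows by flattening with a
    zero guard column so runs cannot cross row boundaries.
    """
    n_rows, n_t = tmat.shape
    best = np.zeros(n_rows)
    for sign in (1.0, -1.0):
        v = np.where(sign * tmat > thr, sign * tmat, 0.0)
        flat = np.concatenate([v, np.zeros((n_rows, 1))], axis=1).ravel()
        pos = flat > 0
        starts = np.flatnonzero(pos & ~np.concatenate(([False], pos[:-1])))
        if starts.size == 0:
            continue
        ends = np.flatnonzero(pos & ~np.concatenate((pos[1:], [False]))) + 1
        cs = np.concatenate(([0.0], np.cumsum(flat)))
        masses = cs[ends] - cs[starts]
        rows = starts // (n_t + 1)
        np.maximum.at(best, rows, masses)
    return best


def _observed_clusters(t: np.ndarray, thr: float) -> list:
    """(start_idx, end_idx_inclusive, mass) of supra-threshold runs."""
    clusters = []
    for sign in (1.0, -1.0):
        above = sign * t > thr
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1))
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [above.size - 1]
        for s, e in zip(starts, ends):
            clusters.append((s, e, float(t[s:e + 1].sum())))
    return sorted(clusters, key=lambda c: c[0])


def cluster_permutation_test(condition: WaveformSet,
                             reference: WaveformSet | None = None,
                             window_ms: tuple[float, float] | None = None,
                             n_permutations: int = 10000,
                             seed=None,
                             cluster_alpha: float = 0.05) -> ClusterResult:
    """Temporal cluster permutation test of condition vs reference (or zero).

    Paired differences are reduced to pointwise one-sample t values inside
    the analysis window; contiguous runs exceeding the two-sided
    ``cluster_alpha`` t threshold form clusters scored by summed t.  The
    family-wise null is the distribution of maximum absolute cluster masses
    under random within-participant sign flips, and each observed cluster's
    p-value is (1 + #{perm max >= |mass|}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        import warnings
        warnings.warn(f"only {n_permutations} permutations; p-values are coarse")
    x = condition.data
    if reference is not None:
        if reference.data.shape != x.shape:
            raise ValueError("condition and reference must pair participants")
        x = x - reference.data
    if window_ms is None:
        window_ms = (condition.times_ms[0], condition.times_ms[-1])
    mask = condition.window_slice(window_ms)
    x = x[:, mask]
    times = condition.times_ms[mask]
    n = x.shape[0]
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1)

    t_obs = _t_from_signflips(x, np.ones((1, n)))[0]
    observed = _observed_clusters(t_obs, thr)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    null_max = _max_cluster_mass_rows(_t_from_signflips(x, flips), thr)
    clusters = []
    for s, e, mass in observed:
        p = (1.0 + np.count_nonzero(null_max >= abs(mass))) / (1.0 + n_permutations)
        clusters.append((float(times[s]), float(times[e]), mass, float(p)))
    return ClusterResult(clusters=clusters, n_permutations=n_permutations,
                         cluster_alpha=cluster_alpha, times_ms=times)


def polynomial_contrasts(n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal linear and quadratic contrast weights for n equispaced bins."""
    if n_bins < 3:
        raise ValueError("need at least 3 bins for linear + quadratic contrasts")
    x = np.arange(n_bins, dtype=float) - (n_bins - 1) / 2.0
    lin = x / np.linalg.norm(x)
    q = x ** 2
    q = q - q.mean()
    q = q - (q @ lin) * lin
    quad = q / np.linalg.norm(q)
    return lin, quad


def polynomial_contrast_test(bin_values: np.ndarray) -> ContrastResult:
    """Linear and quadratic trend tests on a participants x bins matrix.

    Orthogonal polynomial weights are applied per participant; each contrast
    score is tested against zero with a one-sample t, reported as F = t^2
    with df = (1, n - 1).
    """
    y = np.atleast_2d(np.asarray(bin_values, dtype=float))
    n, k = y.shape
    if n < 3 or k < 3:
        raise ValueError("need >= 3 participants and >= 3 bins")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells are not supported")
    lin, quad = polynomial_contrasts(k)
    out = {}
    for name, w in (("linear", lin), ("quadratic", quad)):
        scores = y @ w
        if scores.std(ddof=1) < 1e-12 * max(1.0, np.abs(scores).max()):
            # degenerate: identical scores across participants
            f, p = (0.0, 1.0) if abs(scores.mean()) < 1e-12 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_1samp(scores, 0.0)
            f, p = float(t ** 2), float(p)
        out[name] = (f, p)
    return ContrastResult(linear_f=out["linear"][0], linear_p=out["linear"][1],
                          quadratic_f=out["quadratic"][0],
                          quadratic_p=out["quadratic"][1],
                          df=(1, n - 1), bin_means=y.mean(axis=0))


def rm_anova_oneway(bin_values: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    Returns F, the uncorrected dfs, the GG epsilon, and the GG-corrected
    p-value.  Backed by ``pingouin.rm_anova``.
    """
    y = np.atleast_2d(np.asarray(bin_values, dtype=float))
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 participants and >= 2 bins")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells are not supported")
    if np.allclose(y, y[:, [0]]):
        # identical bins: F is exactly 0, sphericity moot
        return {"F": 0.0, "df1": k - 1, "df2": (k - 1) * (n - 1),
                "epsilon": 1.0, "p_gg": 1.0}
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "bin": np.tile(np.arange(k), n),
        "value": y.ravel()})
    aov = pg.rm_anova(data=long, dv="value", within="bin", subject="subject",
                      correction=True, detailed=False)
    row = aov.iloc[0]
    eps = float(row["eps"])
    p_gg = float(row["p_GG_corr"]) if np.isfinite(row.get("p_GG_corr", np.nan)) \
        else float(row["p_unc"])
    return {"F": float(row["F"]), "df1": float(row["ddof1"]),
            "df2": float(row["ddof2"]), "epsilon": eps, "p_gg": p_gg}


def gg_epsilon(bin_values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a participants x bins matrix."""
    y = np.atleast_2d(np.asarray(bin_values, dtype=float))
    return float(pg.epsilon(pd.DataFrame(y), correction="gg"))


def build_reference_epochs(stream: np.ndarray, onsets, fs: float = 1000.0,
                           start_s: float = 1.9, end_s: float = 3.0,
                           zero_s: float = 2.0) -> WaveformSet:
    """Stimulus-free reference epochs cut from late inter-trial intervals.

    For each onset the segment [start_s, end_s) seconds post-onset is
    extracted and re-referenced so that ``zero_s`` after the original onset
    maps to t = 0.  Segments extending past the stream end are skipped with a
    warning.  Returns one epoch per usable onset (rows of the WaveformSet).
    """
    import warnings
    stream = np.asarray(stream, dtype=float)
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    times = (np.arange(i0, i1) / fs - zero_s) * 1000.0
    rows = []
    for onset in np.asarray(onsets, dtype=int):
        a, b = onset + i0, onset + i1
        if a < 0 or b > stream.size:
            warnings.warn(f"onset {onset}: reference window outside stream; skipped")
            continue
        rows.append(stream[a:b])
    if not rows:
        raise ValueError("no usable reference epochs")
    return WaveformSet(data=np.vstack(rows), times_ms=times,
                       condition="reference")
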