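"""Bias-corrected linear Fisher information for channels and populations.

Linear Fisher information quantifies how well the stimulus can be read out
linearly from a population's spike counts.  For two nearby stimuli
separated by ds (radians), with between-condition mean-count difference
dmu and pooled within-condition covariance S over T channels and N trials
per condition, the finite-sample bias-corrected estimator is

    I = [ dmu' S^-1 dmu * (2N - T - 3)/(2N - 2)  -  2T/N ] / ds^2

which is unbiased for Gaussian counts (the first factor corrects the
inverse-covariance bias, the subtractive term the mean-difference noise).
Contrast differences are mapped to radians by ds = (pi/50) * (c_high -
c_low), i.e. the full 50% contrast span of the task corresponds to pi.

Population curves add channels in descending order of single-channel
information; shuffling permutes trial order independently per channel
within condition, destroying cross-channel noise correlations while
preserving marginals.  Rank-ordered single-channel informations are
summarized by the exponential fit  pred(info) = c + b*(1 - e^(lam*rank)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ContrastPair",
    "DEFAULT_PAIRS",
    "ExpFitParams",
    "equalize_trials",
    "fisher_info",
    "shuffle_trials",
    "population_info_curve",
    "fit_exponential_rank",
    "proportional_gain",
]

#: Contrast span (%) mapped to an angle of pi radians.
FULL_SPAN_CONTRAST = 50.0


@dataclass(frozen=True)
class ContrastPair:
    c_low: float
    c_high: float

    def __post_init__(self):
        if not self.c_high > self.c_low:
            raise ValueError("c_high must exceed c_low")

    @property
    def delta_s(self) -> float:
        """Stimulus separation in radians: (pi/50) * contrast difference."""
        return (np.pi / FULL_SPAN_CONTRAST) * (self.c_high - self.c_low)


DEFAULT_PAIRS = tuple(ContrastPair(lo, hi) for lo, hi in
                      [(10.0, 60.0), (15.0, 50.0), (20.0, 40.0),
                       (25.0, 35.0), (27.0, 33.0), (28.0, 32.0),
                       (29.0, 31.0)])


def equalize_trials(per_day):
    """Equalize trial counts per condition per day, then concatenate days.

    ``per_day`` is an iterable of ``(low, high)`` count matrices (trials x
    channels) for one contrast pair, correct trials only, one entry per
    training day.  Each day both conditions are truncated to the day's
    minimum (chronological prefix, seed-free); days with an empty condition
    are dropped.  Returns the concatenated ``(low, high)`` matrices with
    equal row counts, as if recorded in a single session.
    """
    lows, highs, dropped = [], [], []
    for d, (low, high) in enumerate(per_day):
        low = np.atleast_2d(np.asarray(low, dtype=float))
        high = np.atleast_2d(np.asarray(high, dtype=float))
        k = min(low.shape[0], high.shape[0])
        if k == 0:
            dropped.append(d)
            continue
        lows.append(low[:k])
        highs.append(high[:k])
    if not lows:
        raise ValueError("every day had an empty condition")
    return np.concatenate(lows, axis=0), np.concatenate(highs, axis=0)


def fisher_info(x_low, x_high, delta_s: float) -> float:
    """Bias-corrected linear Fisher information (rad^-2) for a channel set.

    ``x_low`` and ``x_high`` are (N x T) count matrices with equal N; the
    pooled covariance is the average of the two within-condition N-1
    covariance estimates.  Requires N > T + 3 for estimator validity.
    """
    xl = np.atleast_2d(np.asarray(x_low, dtype=float))
    xh = np.atleast_2d(np.asarray(x_high, dtype=float))
    if xl.ndim != 2 or xl.shape != xh.shape:
        raise ValueError("conditions must be equal-shaped (N x T) matrices")
    n, t = xl.shape
    if n <= t + 3:
        raise ValueError(f"need N > T + 3 trials per condition "
                         f"(got N={n}, T={t})")
    dmu = xh.mean(axis=0) - xl.mean(axis=0)
    cov_l = np.cov(xl, rowvar=False, ddof=1).reshape(t, t)
    cov_h = np.cov(xh, rowvar=False, ddof=1).reshape(t, t)
    s = 0.5 * (cov_l + cov_h)
    try:
        raw = float(dmu @ np.linalg.solve(s, dmu))
    except np.linalg.LinAlgError:
        sd = np.sqrt(np.diag(s))
        bad = [int(i) for i in np.flatnonzero(sd < 1e-12)]
        raise ValueError(
            f"singular pooled covariance (zero-variance channels: {bad})")
    correction = (2.0 * n - t - 3.0) / (2.0 * n - 2.0)
    return (raw * correction - 2.0 * t / n) / delta_s**2


def shuffle_trials(x_low, x_high, rng=None):
    """Permute trial order independently per channel within each condition.

    Destroys cross-channel noise correlations; marginal count distributions
    are untouched.  Deterministic given ``rng``.
    """
    rng = np.random.default_rng(rng)
    out = []
    for x in (np.asarray(x_low), np.asarray(x_high)):
        shuffled = np.empty_like(x)
        for j in range(x.shape[1]):
            shuffled[:, j] = x[rng.permutation(x.shape[0]), j]
        out.append(shuffled)
    return out[0], out[1]


def single_channel_infos(x_low, x_high, delta_s: float) -> np.ndarray:
    xl = np.asarray(x_low, dtype=float)
    return np.array([fisher_info(x_low[:, [j]], x_high[:, [j]], delta_s)
                     for j in range(xl.shape[1])])


def population_info_curve(x_low, x_high, delta_s: float, order=None,
                          shuffled: bool = False, rng=None) -> pd.DataFrame:
    """Fisher information at population sizes 1..T.

    Channels are accumulated in descending single-channel information
    (ties broken by channel index) unless an explicit ``order`` is given.
    With ``shuffled=True`` the trial order is first permuted independently
    per channel within condition.
    """
    xl = np.asarray(x_low, dtype=float)
    xh = np.asarray(x_high, dtype=float)
    if shuffled:
        xl, xh = shuffle_trials(xl, xh, rng=rng)
    t = xl.shape[1]
    if order is None:
        infos = single_channel_infos(xl, xh, delta_s)
        order = sorted(range(t), key=lambda j: (-infos[j], j))
    order = list(order)
    rows = []
    for k in range(1, t + 1):
        cols = order[:k]
        rows.append({"size": k,
                     "info": fisher_info(xl[:, cols], xh[:, cols], delta_s),
                     "channels": tuple(cols)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExpFitParams:
    c: float
    b: float
    lam: float
    vaf: float        # % variance accounted for (NaN when TSS = 0)
    flagged: bool = False

    def predict(self, rank):
        rank = np.asarray(rank, dtype=float)
        return self.c + self.b * (1.0 - np.exp(self.lam * rank))


_LAM_STARTS = (-0.5, -0.2, -0.05, 0.05, 0.2, 0.5)


def fit_exponential_rank(infos) -> ExpFitParams:
    """Fit  c + b*(1 - e^(lam*rank))  to rank-ordered single-channel infos.

    Channels are sorted ascending by information (rank 1 = least
    informative).  Constant inputs have undefined variance accounted for
    and are returned flagged with b = 0.
    """
    infos = np.sort(np.asarray(infos, dtype=float))
    k = infos.size
    if k < 5:
        raise ValueError("need >=5 channels")
    ranks = np.arange(1.0, k + 1.0)
    tss = float(np.sum((infos - infos.mean()) ** 2))
    if tss == 0.0:
        return ExpFitParams(c=float(infos[0]), b=0.0, lam=0.0,
                            vaf=float("nan"), flagged=True)

    def residuals(theta):
        c, b, lam = theta
        return c + b * (1.0 - np.exp(lam * ranks)) - infos

    best = None
    span = float(infos[-1] - infos[0])
    for lam0 in _LAM_STARTS:
        denom = 1.0 - np.exp(lam0 * k)
        b0 = span / denom if abs(denom) > 1e-9 else span
        sol = optimize.least_squares(residuals,
                                     [float(infos[0]), b0, lam0])
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    rss, (c, b, lam) = best
    vaf = 100.0 * (1.0 - rss / tss)
    return ExpFitParams(c=float(c), b=float(b), lam=float(lam),
                        vaf=float(vaf), flagged=not best[0] < np.inf)


@dataclass(frozen=True)
class ProportionalGainResult:
    gains: pd.DataFrame          # channel, early, late, gain
    rho: float                   # Spearman rho of early info vs gain
    p: float
    constant: bool = False


def proportional_gain(early_info, late_info, channels=None
                      ) -> ProportionalGainResult:
    """Per-channel proportional information gain (late - early)/early.

    Channels with non-positive early information are excluded (no defined
    proportional gain).  Also reports the Spearman correlation of early
    information against gain across channels: a negative value means
    channels that started with less information gained proportionally
    more.
    """
    early = np.asarray(early_info, dtype=float)
    late = np.asarray(late_info, dtype=float)
    if early.shape != late.shape:
        raise ValueError("early and late info must be paired per channel")
    channels = (np.arange(early.size) if channels is None
                else np.asarray(channels))
    ok = early > 0.0
    if not np.any(ok):
        raise ValueError("all channels excluded (early info <= 0)")
    gain = (late[ok] - early[ok]) / early[ok]
    df = pd.DataFrame({"channel": channels[ok], "early": early[ok],
                       "late": late[ok], "gain": gain})
    if np.ptp(gain) == 0.0 or np.ptp(early[ok]) == 0.0:
        return ProportionalGainResult(gains=df, rho=float("nan"),
                                      p=float("nan"), constant=True)
    rho, p = stats.spearmanr(early[ok], gain)
    return ProportionalGainResult(gains=df, rho=float(rho), p=float(p))
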