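"""Noise and signal correlations and their learning-induced relationship.

Noise correlations are Pearson correlations of two channels' counts across
trials of one stimulus on one day; they are Fisher z-transformed before any
averaging (over contrasts, then over the days of a training period).
Signal correlations are Pearson correlations of the two channels' mean
tuning curves across the 14 test contrasts.  The learning effect of
interest is the slope of noise-z on signal-z within cells defined by
signal-correlation sign x single-channel-information tercile x training
period; whether that slope changed from early to late training is decided
by a resampling test that draws late-sized samples from the pooled
early+late pair distribution and asks whether the observed late slope
falls outside the central 95% range of the resampled slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "noise_correlation",
    "pairwise_noise_correlations",
    "signal_correlation",
    "assign_info_terciles",
    "signal_noise_slope",
    "slope_permutation_test",
    "PermutationSlopeResult",
]

_Z_CLIP = 1.0 - 1e-12


def fisher_z(r):
    """atanh with clipping so |r| = 1 (degenerate cells) stays finite."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -_Z_CLIP, _Z_CLIP))


def inverse_fisher_z(z):
    return np.tanh(np.asarray(z, dtype=float))


def noise_correlation(counts_i, counts_j, min_trials: int = 10):
    """Pearson correlation of two channels' counts within one stimulus cell.

    Returns None (undefined, to be logged) for too few trials or a
    zero-variance channel.
    """
    x = np.asarray(counts_i, dtype=float)
    y = np.asarray(counts_j, dtype=float)
    if x.size < min_trials:
        return None
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def pairwise_noise_correlations(counts, min_trials: int = 10) -> np.ndarray:
    """Upper-triangle pairwise correlation vector of a (trials x channels)
    count matrix; zero-variance channels give NaN entries."""
    counts = np.asarray(counts, dtype=float)
    n_trials, n_ch = counts.shape
    if n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} trials per cell")
    sd = counts.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(counts, rowvar=False)
    r[sd == 0.0, :] = np.nan
    r[:, sd == 0.0] = np.nan
    iu = np.triu_indices(n_ch, k=1)
    return r[iu]


def signal_correlation(tuning_i, tuning_j):
    """Pearson correlation of two mean-rate tuning curves across contrasts.

    Returns None for flat tuning (undefined).
    """
    x = np.asarray(tuning_i, dtype=float)
    y = np.asarray(tuning_j, dtype=float)
    if x.size < 5:
        raise ValueError("need tuning over >=5 contrasts")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def assign_info_terciles(info_by_channel: dict) -> dict:
    """Bottom/middle/top thirds of channels by single-channel information."""
    channels = sorted(info_by_channel)
    order = sorted(channels, key=lambda ch: (info_by_channel[ch], ch))
    n = len(order)
    cut1, cut2 = n // 3, n - n // 3
    tercile = {}
    for i, ch in enumerate(order):
        tercile[ch] = ("bottom" if i < cut1 else
                       "top" if i >= cut2 else "middle")
    return tercile


def signal_noise_slope(signal_z, noise_z, min_pairs: int = 10):
    """OLS slope of noise-z on signal-z within one analysis cell.

    Returns None when the cell holds fewer than ``min_pairs`` pairs (cell
    skipped, to be logged by the caller).
    """
    x = np.asarray(signal_z, dtype=float)
    y = np.asarray(noise_z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        return None
    res = stats.linregress(x, y)
    return float(res.slope)


def _slopes_of_resamples(x, y, idx):
    """Vectorized OLS slopes for resample index matrix (n_perm, n)."""
    xs, ys = x[idx], y[idx]
    mx = xs.mean(axis=1)
    my = ys.mean(axis=1)
    cov = (xs * ys).mean(axis=1) - mx * my
    var = (xs * xs).mean(axis=1) - mx * mx
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / var


@dataclass(frozen=True)
class PermutationSlopeResult:
    slope_early: float
    slope_late: float
    lo: float
    hi: float
    significant: bool
    n_perm: int


def slope_permutation_test(early_signal_z, early_noise_z, late_signal_z,
                           late_noise_z, n_perm: int = 1000,
                           replacement: bool = False,
                           rng=None) -> PermutationSlopeResult:
    """Is the late-period signal-vs-noise slope outside the null 95% range?

    The early and late (signal_z, noise_z) pairs are pooled; ``n_perm``
    resamples of the late-period sample size are drawn from the pool and
    an OLS slope computed for each.  The late slope is deemed
    significantly different from the early one iff it falls outside the
    central 95% range of the resampled slopes.  Deterministic given
    ``rng``.

    By default resamples are drawn *without* replacement (random subsets,
    i.e. random relabelings of the pooled pairs): under the null the
    observed late sample is then exchangeable with every resample, so the
    nominal 5% level is exact.  ``replacement=True`` switches to
    bootstrap-style resampling, which is conservative when the late pairs
    are a sizeable fraction of the pool.
    """
    ex = np.asarray(early_signal_z, dtype=float)
    ey = np.asarray(early_noise_z, dtype=float)
    lx = np.asarray(late_signal_z, dtype=float)
    ly = np.asarray(late_noise_z, dtype=float)
    if ex.size < 2 or lx.size < 2:
        raise ValueError("both periods must be populated")
    px = np.concatenate([ex, lx])
    py = np.concatenate([ey, ly])
    if np.ptp(px) == 0.0:
        raise ValueError("degenerate pooled signal-correlation distribution")
    rng = np.random.default_rng(rng)

    obs_late = signal_noise_slope(lx, ly, min_pairs=2)
    obs_early = signal_noise_slope(ex, ey, min_pairs=2)
    if replacement:
        idx = rng.integers(0, px.size, size=(n_perm, lx.size))
    else:
        idx = np.argsort(rng.random((n_perm, px.size)),
                         axis=1)[:, :lx.size]
    slopes = _slopes_of_resamples(px, py, idx)
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    significant = not (lo <= obs_late <= hi)
    return PermutationSlopeResult(slope_early=obs_early, slope_late=obs_late,
                                  lo=float(lo), hi=float(hi),
                                  significant=bool(significant),
                                  n_perm=n_perm)
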