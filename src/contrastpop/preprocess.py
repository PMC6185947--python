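"""Channel screening, baseline matching and analysis-window selection.

Channel quality is screened with the per-day signal-to-noise ratio

    SNR = (mean_stimulus - mean_spontaneous) / SD_spontaneous

computed for each of the 14 test contrasts (all trials, regardless of the
subject's response); the highest of the 14 values represents the channel
for that day, and a channel enters the analyses iff its daily SNR is >= 1
on at least 80% of recording days.

Baseline matching standardizes spontaneous activity across sessions: a
spike-extraction threshold on candidate-event amplitudes is adjusted by a
staircase (here: bisection, since the supra-threshold rate is monotone in
the threshold) until the spontaneous event rate lands within 1% of a fixed
per-channel target.

The analysis window (default 256 ms) is chosen empirically: candidate
windows on a start-time/length grid are scored by the channel-pooled
sample-vs-test AUROC averaged over all sessions (no early/late
distinction), and the best-scoring window wins, ties going to the earliest
start and then the shortest length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discriminability import auroc

__all__ = [
    "SNRRecord",
    "AnalysisWindow",
    "compute_snr",
    "select_channels",
    "inclusion_report",
    "baseline_match_threshold",
    "find_analysis_window",
]


@dataclass(frozen=True)
class SNRRecord:
    channel: int
    day: int
    snr_per_contrast: tuple
    snr_max: float


@dataclass(frozen=True)
class AnalysisWindow:
    start_ms: float
    length_ms: float = 256.0

    def __post_init__(self):
        if self.start_ms < 0:
            raise ValueError("start_ms must be >= 0")
        if self.start_ms + self.length_ms > 512.0:
            raise ValueError("window must fit in the 512 ms stimulus epoch")


def compute_snr(session, channel: int, contrast_levels=None) -> SNRRecord:
    """Per-contrast SNR of one channel on one day.

    The stimulus mean comes from the test-epoch counts of each contrast
    condition; the spontaneous mean and SD from the pre-test counts of all
    the day's trials (correct and error alike).  A zero spontaneous SD
    leaves the SNR undefined and raises.
    """
    spont = session.epoch("spont")[:, channel].astype(float)
    test = session.epoch("test")[:, channel].astype(float)
    # rates in events/s so stimulus and spontaneous windows are comparable
    spont_rate = spont / (session_spont_seconds(session))
    test_rate = test / (session_window_seconds(session))
    sd_spont = float(np.std(spont_rate, ddof=1))
    if sd_spont == 0.0:
        raise ValueError(
            f"channel {channel}, day {session.day}: zero spontaneous SD, "
            "SNR undefined")
    mean_spont = float(np.mean(spont_rate))
    levels = (np.unique(session.test_contrast) if contrast_levels is None
              else np.asarray(contrast_levels, dtype=float))
    snrs = []
    for c in levels:
        sel = session.test_contrast == c
        if np.sum(sel) < 2:
            raise ValueError(f"need >=2 trials at contrast {c}")
        snrs.append((float(np.mean(test_rate[sel])) - mean_spont) / sd_spont)
    return SNRRecord(channel=channel, day=session.day,
                     snr_per_contrast=tuple(snrs), snr_max=max(snrs))


def session_window_seconds(session) -> float:
    return session.ground_truth.get("window_s", 0.256)


def session_spont_seconds(session) -> float:
    return session.ground_truth.get("spont_window_s", 0.300)


def select_channels(records, snr_threshold: float = 1.0,
                    min_day_fraction: float = 0.8) -> list:
    """Channel ids whose daily snr_max >= threshold on >= 80% of days.

    The 80% boundary counts as a pass.  ``records`` is an iterable of
    :class:`SNRRecord` covering every channel x day combination.
    """
    by_channel = {}
    for rec in records:
        by_channel.setdefault(rec.channel, []).append(rec.snr_max)
    included = []
    for ch in sorted(by_channel):
        passing = np.mean([s >= snr_threshold for s in by_channel[ch]])
        if passing >= min_day_fraction:
            included.append(ch)
    return included


def inclusion_report(records, snr_threshold: float = 1.0,
                     min_day_fraction: float = 0.8) -> pd.DataFrame:
    by_channel = {}
    for rec in records:
        by_channel.setdefault(rec.channel, []).append(rec.snr_max)
    rows = []
    for ch in sorted(by_channel):
        days_passing = int(np.sum([s >= snr_threshold
                                   for s in by_channel[ch]]))
        frac = days_passing / len(by_channel[ch])
        rows.append({"channel": ch, "days_passing": days_passing,
                     "fraction": frac,
                     "included": frac >= min_day_fraction})
    return pd.DataFrame(rows)


class StaircaseError(RuntimeError):
    """Raised when the baseline-matching target rate is unattainable."""


def baseline_match_threshold(amplitudes, duration_s: float,
                             target_rate: float, rel_tol: float = 0.01,
                             max_iter: int = 100):
    """Threshold on event amplitudes matching a target spontaneous rate.

    Bisects the threshold (the supra-threshold rate is monotone decreasing
    in it) until |achieved - target| / target <= 1%.  Returns
    ``(threshold, achieved_rate)``.  A target at or above the total event
    rate returns a threshold below the minimum amplitude (keep everything);
    a target that cannot be reached within ``max_iter`` halvings raises
    :class:`StaircaseError`.
    """
    amps = np.sort(np.asarray(amplitudes, dtype=float))
    if amps.size == 0 or duration_s <= 0 or target_rate <= 0:
        raise ValueError("need events, a positive duration and target rate")
    total_rate = amps.size / duration_s
    if target_rate >= total_rate:
        if (target_rate - total_rate) / target_rate > rel_tol:
            raise StaircaseError(
                f"target {target_rate}/s exceeds total event rate "
                f"{total_rate}/s")
        return float(amps[0] - 1.0), total_rate

    def rate(th):
        return float(np.sum(amps > th)) / duration_s

    lo, hi = float(amps[0] - 1.0), float(amps[-1])
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) / target_rate <= rel_tol:
            return mid, r
        if r > target_rate:
            lo = mid
        else:
            hi = mid
    raise StaircaseError(
        f"staircase did not converge to within {rel_tol:.0%} of "
        f"{target_rate}/s in {max_iter} iterations")


_DEFAULT_STARTS = np.arange(0.0, 513.0, 8.0)
_DEFAULT_LENGTHS = (50.0, 100.0, 150.0, 200.0, 250.0, 256.0)


def _window_score(binned, start_ms: float, length_ms: float) -> float:
    """Session-averaged discriminability of a candidate window.

    Per session, counts are summed in the window for the sample and test
    epochs and the per-contrast sample-vs-test AUROCs are folded about
    chance (|AUROC - 0.5|) and averaged, so contrasts below and above the
    boundary both contribute.
    """
    scores = []
    for b in binned:
        edges = np.arange(0.0, b.sample.shape[1] * b.bin_ms + 0.5 * b.bin_ms,
                          b.bin_ms)
        i0 = int(np.searchsorted(edges, start_ms, side="left"))
        i1 = int(np.searchsorted(edges, start_ms + length_ms, side="left"))
        s = b.sample[:, i0:i1].sum(axis=1)
        t = b.test[:, i0:i1].sum(axis=1)
        per_contrast = []
        for c in np.unique(b.test_contrast):
            sel = b.test_contrast == c
            per_contrast.append(abs(auroc(s[sel], t[sel]) - 0.5))
        scores.append(np.mean(per_contrast))
    return float(np.mean(scores))


def find_analysis_window(binned, starts=None, lengths=None):
    """Exhaustive grid search for the most informative analysis window.

    ``binned`` is a list of channel-pooled :class:`BinnedPopulation`
    sessions.  Returns ``(AnalysisWindow, scores)`` where ``scores`` is the
    full grid as a DataFrame.  Ties are broken by earliest start, then
    shortest length; the result is invariant to channel permutation because
    activity is pooled before scoring.
    """
    starts = _DEFAULT_STARTS if starts is None else np.asarray(starts, float)
    lengths = _DEFAULT_LENGTHS if lengths is None else tuple(lengths)
    rows = []
    best = None
    for start in starts:
        for length in sorted(lengths):
            if start + length > 512.0:
                continue
            score = _window_score(binned, start, length)
            rows.append({"start_ms": start, "length_ms": length,
                         "score": score})
            if best is None or score > best[0] + 1e-12:
                best = (score, start, length)
    if best is None:
        raise ValueError("no candidate window fits the 512 ms epoch")
    _, start, length = best
    return AnalysisWindow(start_ms=start, length_ms=length), pd.DataFrame(rows)
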