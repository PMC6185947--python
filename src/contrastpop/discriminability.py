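"""Ideal-observer discriminability: AUROC, COBE, neurometric fits and PNE.

Discriminability between two stimulus-conditioned spike-count distributions
is measured by the area under the ROC curve, estimated as the tie-corrected
rank statistic P(b > a) + 1/2 P(b = a) over all cross pairs (0.5 = chance,
1 = perfect).  For the 2-AFC design, where sample and test stimuli occur
within the same trial, the count-based estimator (COBE) estimates the same
probability from *within-trial* pairs only, so that slow shared gain
fluctuations that inflate both counts together cancel out.

Neurometric functions (AUROC vs test contrast) are fitted with the
four-parameter Weibull

    y(x) = 1 - delta - gamma * exp(-(x/alpha)^beta)

whose slope at 30% contrast is  beta*gamma*(30/alpha)^beta *
exp(-(30/alpha)^beta) / 30.  The point of neuronal equality (PNE) is the
contrast at which the fitted curve crosses 0.5, i.e. where sample- and
test-evoked activity are indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tuning import BOUNDARY_CONTRAST

__all__ = [
    "auroc",
    "cobe",
    "NeurometricParams",
    "weibull",
    "fit_neurometric",
    "compute_pne",
    "pne_inclusion",
    "test_test_auroc",
    "early_late_difference",
]


def auroc(a, b) -> float:
    """Tie-corrected AUROC: P(b > a) + 1/2 P(b = a) over all cross pairs.

    ``a`` is the reference distribution, ``b`` the comparison; identical
    multisets give exactly 0.5 and auroc(a, b) + auroc(b, a) == 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_b = float(np.sum(ranks[a.size:])) - b.size * (b.size + 1) / 2.0
    return u_b / (a.size * b.size)


def cobe(sample_counts, test_counts) -> float:
    """Count-based estimator of P(test > sample) from within-trial pairs.

    Both arrays must come from the *same* trials, in trial order; the
    pairing is the estimator's defining contract.  Within-trial ties count
    one half, mirroring the AUROC tie correction.
    """
    s = np.asarray(sample_counts, dtype=float).ravel()
    t = np.asarray(test_counts, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("need at least one trial")
    if s.shape != t.shape:
        raise ValueError(
            "sample and test counts must be paired per trial "
            f"(got {s.size} vs {t.size} trials)")
    return float(np.mean(t > s) + 0.5 * np.mean(t == s))


def weibull(x, alpha, beta, gamma, delta):
    """Four-parameter Weibull neurometric function y(x)."""
    x = np.asarray(x, dtype=float)
    return 1.0 - delta - gamma * np.exp(-np.power(x / alpha, beta))


_ALPHA_STARTS = (15.0, 33.0, 60.0)
_BETA_STARTS = (1.0, 3.0, 6.0)
_BOUNDS_LO = np.array([5.0, 0.2, 0.0, 0.0])
_BOUNDS_HI = np.array([100.0, 10.0, 1.0, 0.5])


@dataclass(frozen=True)
class NeurometricParams:
    """Fitted Weibull parameters for one channel/day neurometric function."""

    alpha: float   # scale: contrast at 63% of the range (%)
    beta: float    # shape exponent
    gamma: float   # range
    delta: float   # 1 - upper asymptote
    rss: float = float("nan")
    flagged: bool = False

    def predict(self, x):
        return weibull(x, self.alpha, self.beta, self.gamma, self.delta)

    @property
    def slope30(self) -> float:
        """Analytic slope of the fitted curve at 30% contrast."""
        r = (BOUNDARY_CONTRAST / self.alpha) ** self.beta
        return self.beta * self.gamma * r * np.exp(-r) / BOUNDARY_CONTRAST


def fit_neurometric(contrasts, values) -> NeurometricParams:
    """Fit the four-parameter Weibull to AUROC-vs-contrast data.

    A Gaussian observation model (least squares) is used: the y-values are
    AUROC estimates, not Bernoulli trials.  The fit is deterministic given
    the data (fixed multi-start grid, bounded least squares).  Fits whose
    shape parameter lands on a bound (typically non-monotone data) are
    flagged.
    """
    x = np.asarray(contrasts, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("contrasts and values must have matching shapes")
    if np.unique(x).size < 6:
        raise ValueError("need AUROC values at >=6 contrasts")

    gamma0 = float(np.clip(np.ptp(y), 0.05, 1.0))
    delta0 = float(np.clip(1.0 - np.max(y), 0.0, 0.5))

    def residuals(theta):
        return weibull(x, *theta) - y

    best = None
    for alpha0 in _ALPHA_STARTS:
        for beta0 in _BETA_STARTS:
            theta0 = np.clip([alpha0, beta0, gamma0, delta0],
                             _BOUNDS_LO, _BOUNDS_HI)
            sol = optimize.least_squares(residuals, theta0,
                                         bounds=(_BOUNDS_LO, _BOUNDS_HI))
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    rss, (alpha, beta, gamma, delta) = best
    flagged = bool(beta >= _BOUNDS_HI[1] - 1e-3 or beta <= _BOUNDS_LO[1] + 1e-3)
    return NeurometricParams(alpha=float(alpha), beta=float(beta),
                             gamma=float(gamma), delta=float(delta),
                             rss=rss, flagged=flagged)


def compute_pne(params: NeurometricParams, lo: float = 10.0,
                hi: float = 60.0, tol: float = 1e-9):
    """Point of neuronal equality: root of y(x) = 0.5 on [lo, hi], or None.

    Returns ``None`` (undefined, not an error) when the fitted curve does
    not span 0.5 over the tested contrast range.  The fitted Weibull is
    monotone for beta > 0, so the root is unique when it exists.
    """
    f_lo = params.predict(lo) - 0.5
    f_hi = params.predict(hi) - 0.5
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    root = optimize.brentq(lambda x: params.predict(x) - 0.5, lo, hi,
                           xtol=tol)
    return float(root)


def pne_inclusion(pne_by_day, min_fraction: float = 0.8) -> bool:
    """Channel-level rule: PNE must be defined on >= 80% of sessions."""
    defined = [p is not None and np.isfinite(p) for p in pne_by_day]
    if not defined:
        raise ValueError("no sessions provided")
    return float(np.mean(defined)) >= min_fraction


def test_test_auroc(counts_low, counts_high, reversed_channel: bool = False
                    ) -> float:
    """Pooled AUROC between two test-contrast conditions.

    Trials are pooled across days (within-trial pairing does not exist
    between two test conditions, so the paired estimator is not applicable
    here).  Reversed-tuned channels are reported as 1 - AUROC so that
    'better discrimination in the expected direction' exceeds 0.5 for every
    channel.
    """
    value = auroc(counts_low, counts_high)
    return 1.0 - value if reversed_channel else value


@dataclass(frozen=True)
class EarlyLateResult:
    per_channel: pd.DataFrame   # channel, early, late, diff
    statistic: float
    p: float


def early_late_difference(records: pd.DataFrame, early_days, late_days
                          ) -> EarlyLateResult:
    """Early-vs-late comparison of per-channel discriminability values.

    ``records`` needs columns ``channel``, ``day`` and ``value`` (e.g. the
    AUROC difference between a mirrored contrast pair).  Values are averaged
    separately over the early and late day sets for each channel and the
    channel-level pairs enter a two-sided Wilcoxon signed-rank test.
    """
    early_days, late_days = list(early_days), list(late_days)
    if len(early_days) < 5 or len(late_days) < 5:
        raise ValueError("need >=5 days in each period")
    rows = []
    for ch, grp in records.groupby("channel"):
        e = grp.loc[grp["day"].isin(early_days), "value"].mean()
        l = grp.loc[grp["day"].isin(late_days), "value"].mean()
        rows.append({"channel": ch, "early": e, "late": l, "diff": l - e})
    per_channel = pd.DataFrame(rows)
    diffs = per_channel["diff"].to_numpy()
    if np.allclose(diffs, 0.0):
        return EarlyLateResult(per_channel, statistic=float("nan"), p=1.0)
    stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    return EarlyLateResult(per_channel, statistic=float(stat), p=float(p))
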