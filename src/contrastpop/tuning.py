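"""Contrast-response-function fitting and learning-trend statistics.

A channel's firing rate as a function of stimulus contrast (its contrast
response function, CRF) is modelled with the Naka-Rushton equation

    R(C) = Rmax * C^n / (C^n + C50^n) + M

where ``Rmax`` is the response range, ``C50`` the semi-saturation contrast,
``n`` the exponent controlling steepness and ``M`` the spontaneous offset
(all rates in spikes/s, contrasts in %).  Channels whose rate *decreases*
with contrast ("reversed tuning") use the decreasing form
``R(C) = Rmax * (1 - C^n/(C^n + C50^n)) + M``.

The quantity of interest for a categorization task with a 30% boundary is
the tangent slope of the fitted CRF at 30% contrast,

    slope(C) = n * Rmax * C^(n-1) * C50^n / (C^n + C50^n)^2

evaluated at C = 30 (negated for reversed channels).  Learning trends are
quantified by Spearman rank correlation of channel-averaged parameters
against session number.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BOUNDARY_CONTRAST",
    "CRFParams",
    "TrendResult",
    "naka_rushton",
    "naka_rushton_slope",
    "fit_naka_rushton",
    "classify_reversed",
    "rectified_slope30",
    "distance_to_boundary",
    "trend_test",
]

#: Sample contrast / categorization boundary (% contrast).
BOUNDARY_CONTRAST = 30.0


def naka_rushton(c, rmax, c50, n, m, reversed_tuning=False):
    """Evaluate the Naka-Rushton CRF at contrast(s) ``c`` (%)."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, n)
    frac = cn / (cn + c50**n)
    if reversed_tuning:
        frac = 1.0 - frac
    return rmax * frac + m


def naka_rushton_slope(c, rmax, c50, n, m=0.0, reversed_tuning=False):
    """Tangent slope dR/dC of the Naka-Rushton CRF (spikes/s per % contrast)."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, n)
    s = n * rmax * np.power(c, n - 1.0) * c50**n / (cn + c50**n) ** 2
    return -s if reversed_tuning else s


@dataclass(frozen=True)
class CRFParams:
    """Fitted (or ground-truth) Naka-Rushton parameters for one channel/day.

    ``slope30`` is the signed tangent slope at the 30% boundary; it is
    negative for reversed-tuned channels.  ``flat`` marks degenerate fits
    (no rate modulation), for which ``slope30`` is zero by convention.
    """

    rmax: float
    c50: float
    n: float
    m: float
    reversed_tuning: bool = False
    rss: float = float("nan")
    flat: bool = False

    def __post_init__(self):
        if not self.flat:
            if not (0.0 < self.c50 < 100.0):
                raise ValueError(f"C50 must lie in (0, 100), got {self.c50}")
            if self.n <= 0:
                raise ValueError(f"exponent n must be positive, got {self.n}")

    def rate(self, c):
        if self.flat:
            return np.broadcast_to(np.float64(self.m), np.shape(np.asarray(c))).copy()
        return naka_rushton(c, self.rmax, self.c50, self.n, self.m,
                            self.reversed_tuning)

    def slope(self, c):
        if self.flat:
            return np.zeros_like(np.asarray(c, dtype=float))
        return naka_rushton_slope(c, self.rmax, self.c50, self.n,
                                  reversed_tuning=self.reversed_tuning)

    @property
    def slope30(self) -> float:
        return float(self.slope(BOUNDARY_CONTRAST))


# Fixed 3x3x3 (C50 x n x Rmax-scale) start grid; the best starts by initial
# RSS are refined with bounded least squares.  Deterministic by construction.
_C50_STARTS = (15.0, 30.0, 60.0)
_N_STARTS = (1.0, 2.0, 5.0)
_RMAX_SCALES = (0.5, 1.0, 2.0)
_N_REFINE = 3


def _fit_one_form(contrasts, rates, weights, reversed_tuning):
    rate_min, rate_max = float(np.min(rates)), float(np.max(rates))
    span = max(rate_max - rate_min, 1e-9)
    lb = np.array([1e-9, 1.0, 0.1, 0.0])
    ub = np.array([10.0 * max(rate_max, 1e-9), 100.0, 10.0, rate_min + 1.0])
    sw = np.sqrt(weights)

    def residuals(theta):
        r = naka_rushton(contrasts, *theta, reversed_tuning=reversed_tuning)
        return sw * (r - rates)

    starts = []
    for c50 in _C50_STARTS:
        for n in _N_STARTS:
            for scale in _RMAX_SCALES:
                theta0 = np.clip(
                    [scale * span, c50, n, rate_min], lb, ub)
                starts.append((float(np.sum(residuals(theta0) ** 2)), theta0))
    starts.sort(key=lambda t: t[0])

    best = None
    for _, theta0 in starts[:_N_REFINE]:
        sol = optimize.least_squares(residuals, theta0, bounds=(lb, ub))
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    rss, (rmax, c50, n, m) = best
    return CRFParams(rmax=rmax, c50=c50, n=n, m=m,
                     reversed_tuning=reversed_tuning, rss=rss)


def fit_naka_rushton(contrasts, rates, weights=None) -> CRFParams:
    """Least-squares Naka-Rushton fit to per-contrast firing rates.

    Parameters
    ----------
    contrasts : array-like of % contrast (>=5 distinct values required)
    rates : array-like of firing rates (spikes/s), one per contrast
    weights : optional per-contrast weights (e.g. trial counts)

    Both the increasing and the decreasing (reversed-tuning) form are fitted
    from a fixed multi-start grid and the lower-residual form is returned,
    so the fit itself is deterministic given the data.  All-equal rates
    yield a flat fit flagged via ``flat`` with ``slope30 == 0``.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if contrasts.shape != rates.shape:
        raise ValueError("contrasts and rates must have matching shapes")
    if np.unique(contrasts).size < 5:
        raise ValueError("need rate estimates at >=5 distinct contrasts")
    weights = (np.ones_like(rates) if weights is None
               else np.asarray(weights, dtype=float))
    if np.ptp(rates) == 0.0:
        return CRFParams(rmax=0.0, c50=BOUNDARY_CONTRAST, n=1.0,
                         m=float(rates[0]), rss=0.0, flat=True)

    fwd = _fit_one_form(contrasts, rates, weights, reversed_tuning=False)
    rev = _fit_one_form(contrasts, rates, weights, reversed_tuning=True)
    return fwd if fwd.rss <= rev.rss else rev


def classify_reversed(params_by_day) -> bool:
    """A channel is 'reversed tuned' iff its across-day mean slope30 < 0."""
    slopes = [p.slope30 for p in params_by_day]
    if not slopes:
        raise ValueError("need at least one fitted day")
    return float(np.mean(slopes)) < 0.0


def rectified_slope30(params: CRFParams, reversed_channel: bool) -> float:
    """slope30 with the sign convention used for population pooling.

    Channels classified as reversed have their slope multiplied by -1 so a
    steepening tuning curve contributes positively regardless of tuning sign.
    """
    return -params.slope30 if reversed_channel else params.slope30


def distance_to_boundary(x) -> float:
    """|x - 30|: distance of a contrast parameter from the boundary (%)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("contrast parameter must be finite")
    out = np.abs(x - BOUNDARY_CONTRAST)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p: float
    n: int
    constant: bool = False


def trend_test(values, days=None) -> TrendResult:
    """Spearman rank correlation of channel-averaged values vs session index.

    ``values`` holds one (channel-averaged) number per session, in session
    order; ties are handled by midranks.  A constant series has no defined
    rank correlation and is flagged instead of erroring.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need >=5 sessions for a trend test")
    days = (np.arange(1, values.size + 1) if days is None
            else np.asarray(days, dtype=float))
    if np.ptp(values) == 0.0:
        return TrendResult(rho=float("nan"), p=float("nan"), n=values.size,
                           constant=True)
    rho, p = stats.spearmanr(days, values)
    return TrendResult(rho=float(rho), p=float(p), n=values.size)
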