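"""Choice-probability analysis, standard and sample-subtracted.

Choice probability (CP) is the AUROC between the two test-epoch activity
distributions obtained by conditioning trials of one test contrast on the
subject's upcoming choice.  CP > 0.5 means higher activity predicts the
"higher test contrast" saccade; reversed-tuned channels are stored as
1 - CP so the predictive direction is uniform across channels.  The
sample-subtracted variant computes the same AUROC on per-trial
(test - sample) count differences, removing slow shared-gain fluctuations
and asking whether choices track the within-trial activity *difference*
rather than the absolute test-evoked level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discriminability import auroc

__all__ = [
    "normalize_choices",
    "choice_probability",
    "diff_choice_probability",
    "pool_cp_early_late",
]

#: Minimum trials per choice group for a CP to be calculable.
MIN_PER_GROUP = 3


def normalize_choices(choices) -> np.ndarray:
    """Boolean 'chose higher' array from bools or 'higher'/'lower' labels."""
    arr = np.asarray(choices)
    if arr.dtype == bool:
        return arr
    return np.asarray([str(c) == "higher" for c in arr], dtype=bool)


def choice_probability(test_counts, choices, reversed_channel: bool = False,
                       min_per_group: int = MIN_PER_GROUP):
    """CP for one channel/day/contrast, or None when a group is too small.

    Positive class is the 'higher contrast' choice: CP = P(count on a
    higher-choice trial > count on a lower-choice trial) + 1/2 ties.
    Reversed-tuned channels are reported as 1 - CP.
    """
    counts = np.asarray(test_counts, dtype=float)
    higher = normalize_choices(choices)
    n_hi, n_lo = int(higher.sum()), int((~higher).sum())
    if n_hi < min_per_group or n_lo < min_per_group:
        return None
    cp = auroc(counts[~higher], counts[higher])
    return 1.0 - cp if reversed_channel else cp


def diff_choice_probability(test_counts, sample_counts, choices,
                            reversed_channel: bool = False,
                            min_per_group: int = MIN_PER_GROUP):
    """Sample-subtracted CP on per-trial (test - sample) differences.

    Within-trial pairing of the two epochs must be preserved.
    """
    t = np.asarray(test_counts, dtype=float)
    s = np.asarray(sample_counts, dtype=float)
    if t.shape != s.shape:
        raise ValueError("test and sample counts must be paired per trial")
    return choice_probability(t - s, choices, reversed_channel,
                              min_per_group)


@dataclass(frozen=True)
class CPPoolResult:
    per_contrast: pd.DataFrame   # contrast, mean_early, mean_late, t, p, n
    long_table: pd.DataFrame     # channel, period, contrast, cp


def pool_cp_early_late(records: pd.DataFrame, early_days, late_days
                       ) -> CPPoolResult:
    """Pool CPs over the first/last 5 days and test the learning shift.

    ``records`` needs columns ``channel``, ``day``, ``contrast``, ``cp``
    (rows with undefined CP omitted).  Per contrast, channel-level early
    and late means enter a one-sided paired t-test in the direction "CP
    more indicative of the choice late".  Under this package's convention
    (CP > 0.5 means higher activity predicts the higher-contrast saccade,
    after the reversed-tuning flip) a tighter activity-choice coupling
    raises CP at *every* test contrast, so the alternative is 'greater'
    throughout.  The long period x contrast table is returned for
    consumption by a standard two-way ANOVA routine.
    """
    early_days, late_days = list(early_days), list(late_days)
    if len(early_days) < 5 or len(late_days) < 5:
        raise ValueError("need >=5 days in each period")

    long_rows = []
    per_contrast = []
    for contrast, grp in records.groupby("contrast"):
        pairs = []
        for ch, g in grp.groupby("channel"):
            e = g.loc[g["day"].isin(early_days), "cp"]
            l = g.loc[g["day"].isin(late_days), "cp"]
            if e.empty or l.empty:
                continue
            pairs.append((ch, e.mean(), l.mean()))
            long_rows.append({"channel": ch, "period": "early",
                              "contrast": contrast, "cp": e.mean()})
            long_rows.append({"channel": ch, "period": "late",
                              "contrast": contrast, "cp": l.mean()})
        if not pairs:
            continue
        early = np.array([p[1] for p in pairs])
        late = np.array([p[2] for p in pairs])
        alternative = "greater"
        diffs = late - early
        if np.ptp(diffs) == 0.0:
            # degenerate paired t: all differences identical
            if diffs[0] == 0.0:
                t_stat, p = float("nan"), 0.5
            else:
                sign_ok = ((diffs[0] > 0) == (alternative == "greater"))
                t_stat, p = float("inf") if sign_ok else float("-inf"), \
                    0.0 if sign_ok else 1.0
        else:
            t_stat, p = stats.ttest_rel(late, early, alternative=alternative)
        per_contrast.append({"contrast": contrast,
                             "mean_early": float(early.mean()),
                             "mean_late": float(late.mean()),
                             "t": float(t_stat), "p": float(p),
                             "n": len(pairs)})
    return CPPoolResult(per_contrast=pd.DataFrame(per_contrast),
                        long_table=pd.DataFrame(long_rows))
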