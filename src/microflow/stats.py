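"""Group statistics for longitudinal microcirculation studies.

Small groups of subjects (typically five) are measured at a shared grid
of timepoints around an intervention. This layer provides per-group
per-timepoint mean +/- SD summaries, a range-normalize-then-center
transform for comparing trends across quantities with different units,
and per-timepoint paired Student t-tests of each follow-up against the
pre-intervention baseline at a configurable alpha (default 0.1).

The test is paired because the same subjects are measured at baseline
and follow-up; an unpaired Welch variant is available via
``paired=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TimelineEntry",
    "group_summary",
    "normalize_centralize",
    "ttest_vs_baseline",
    "significance_timeline",
]


@dataclass
class TimelineEntry:
    """One timepoint of a significance timeline."""

    timepoint: float
    t_statistic: float
    p_value: float
    flag: int  # 1 iff p < alpha
    n: int
    alpha: float


def group_summary(table: pd.DataFrame, quantity: str) -> pd.DataFrame:
    """Per-(group, timepoint) mean and sample SD (ddof=1).

    Cells with a single subject keep their mean but report SD as NaN;
    empty cells are simply absent (missing, never zero).
    """
    sub = table[table["quantity"] == quantity]
    g = sub.groupby(["group", "timepoint_h"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    return out.reset_index()


def normalize_centralize(series, mode: str = "range") -> np.ndarray:
    """Normalize then center a per-timepoint series.

    mode="range" (default): x -> (x - mean(x)) / (max(x) - min(x)), so
    the output has mean 0 and range exactly 1 and is invariant to any
    positive affine transform of the input. mode="zscore" divides by
    the sample SD instead.
    """
    x = np.asarray(series, dtype=float)
    if mode == "range":
        span = x.max() - x.min()
        if span == 0:
            raise ValueError("zero range: constant series cannot be normalized")
        return (x - x.mean()) / span
    if mode == "zscore":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance: constant series cannot be normalized")
        return (x - x.mean()) / sd
    raise ValueError(f"unknown mode {mode!r}")


def ttest_vs_baseline(table: pd.DataFrame, group: str, quantity: str,
                      timepoint: float, baseline_timepoint: float,
                      alpha: float = 0.1, paired: bool = True) -> TimelineEntry:
    """Two-sided Student t-test of one timepoint against baseline.

    Paired (default): t on per-subject differences with n-1 df, using
    only subjects present at both timepoints. If every difference is
    exactly zero the result is the null itself (t=0, p=1).
    """
    sub = table[(table["quantity"] == quantity) & (table["group"] == group)]
    base = sub[sub["timepoint_h"] == baseline_timepoint].set_index("subject_id")["value"]
    post = sub[sub["timepoint_h"] == timepoint].set_index("subject_id")["value"]
    if paired:
        common = base.index.intersection(post.index)
        n = len(common)
        if n < 2:
            raise ValueError("paired test needs >= 2 subjects at both timepoints")
        diff = (post.loc[common] - base.loc[common]).to_numpy(dtype=float)
        if np.all(diff == 0):
            t_stat, p = 0.0, 1.0
        else:
            sd = diff.std(ddof=1)
            if sd == 0:
                t_stat = np.inf * np.sign(diff.mean())
                p = 0.0
            else:
                t_stat = diff.mean() / (sd / np.sqrt(n))
                p = 2.0 * sps.t.sf(abs(t_stat), df=n - 1)
    else:
        a = base.to_numpy(dtype=float)
        b = post.to_numpy(dtype=float)
        n = min(len(a), len(b))
        if len(a) < 2 or len(b) < 2:
            raise ValueError("unpaired test needs >= 2 subjects per timepoint")
        t_stat, p = sps.ttest_ind(b, a, equal_var=False)
    return TimelineEntry(timepoint=float(timepoint), t_statistic=float(t_stat),
                         p_value=float(p), flag=int(p < alpha), n=int(n),
                         alpha=alpha)


def significance_timeline(table: pd.DataFrame, group: str, quantity: str,
                          baseline_timepoint: float, alpha: float = 0.1,
                          paired: bool = True) -> list:
    """Baseline-vs-timepoint tests at every non-baseline timepoint."""
    sub = table[(table["quantity"] == quantity) & (table["group"] == group)]
    tps = sorted(t for t in sub["timepoint_h"].unique()
                 if t != baseline_timepoint)
    return [ttest_vs_baseline(table, group, quantity, tp, baseline_timepoint,
                              alpha=alpha, paired=paired) for tp in tps]
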