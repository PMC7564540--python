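"""Cross-condition analysis: pattern classification, cooperativity ratios,
and the methylation-vs-demethylation rank-sum comparison.

Methylation-class distributions fall into three recognisable shapes:
pattern A (unimodal, peaked at a poorly methylated class), pattern B
(unimodal, peaked at a highly methylated class), and pattern C (bimodal,
with one peak at a low and one at a high class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epialleles import ConditionDistribution
from .fitting import FitResult

__all__ = [
    "PatternLabel",
    "RankSumResult",
    "classify_pattern",
    "cooperativity_ratios",
    "rank_sum_test",
]


@dataclass(frozen=True)
class PatternLabel:
    """Shape class of a condition distribution.

    ``label`` is "A", "B", "C", or "unresolved" (more than two surviving
    peaks); ``peak_classes`` lists the class indices of the surviving peaks.
    """

    label: str
    peak_classes: tuple


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney rank-sum comparison of two ratio samples.

    ``w`` is the first-sample U statistic: the number of pairs (x_i, y_j)
    with x_i > y_j, counting ties as 1/2.
    """

    w: float
    p_value: float
    n1: int
    n2: int
    method: str


def _local_maxima(d: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau is represented by its first index."""
    n = len(d)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        left_ok = i == 0 or d[i - 1] < d[i]
        right_ok = j == n - 1 or d[j + 1] < d[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def classify_pattern(
    condition: ConditionDistribution,
    min_peak: float = 0.05,
    min_valley_drop: float = 0.2,
) -> PatternLabel:
    """Classify a condition distribution as pattern A, B or C.

    Peaks are local maxima of D_n with frequency at least ``min_peak``;
    two adjacent peaks are kept separate only if the valley between them
    drops at least ``min_valley_drop`` times the smaller peak below it,
    otherwise the smaller peak is absorbed.  One surviving peak in the
    lower half of the classes gives A, in the upper half B; two surviving
    peaks give C.  A single peak exactly at N/2 is resolved by comparing
    the mass below and above N/2 (tie -> A).  More than two surviving
    peaks yield the explicit label "unresolved".
    """
    d = condition.d
    n_sites = condition.n_sites
    peaks = [i for i in _local_maxima(d) if d[i] >= min_peak]

    # valley criterion: absorb the smaller of any insufficiently separated pair
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for a, b in zip(peaks, peaks[1:]):
            valley = d[a + 1 : b].min() if b > a + 1 else min(d[a], d[b])
            smaller = min(d[a], d[b])
            if valley > (1.0 - min_valley_drop) * smaller:
                drop = a if d[a] < d[b] else b if d[b] < d[a] else b
                peaks.remove(drop)
                changed = True
                break

    if len(peaks) == 2:
        return PatternLabel(label="C", peak_classes=tuple(peaks))
    if len(peaks) == 1:
        peak = peaks[0]
        half = n_sites / 2.0
        if peak < half:
            return PatternLabel(label="A", peak_classes=(peak,))
        if peak > half:
            return PatternLabel(label="B", peak_classes=(peak,))
        low = d[: peak].sum()
        high = d[peak + 1 :].sum()
        label = "B" if high > low else "A"
        return PatternLabel(label=label, peak_classes=(peak,))
    return PatternLabel(label="unresolved", peak_classes=tuple(peaks))


def cooperativity_ratios(fits: Sequence[FitResult]):
    """Tabulate cooperativity ratios alpha/P and beta/Q across conditions.

    Non-converged fits are excluded with a warning.  Returns a DataFrame
    with one row per condition and a summary dict holding the mean and
    sample standard deviation of each ratio column.
    """
    rows = []
    excluded = []
    for fit in fits:
        if not fit.converged:
            excluded.append(fit.condition_id)
            continue
        rows.append(
            {
                "condition_id": fit.condition_id,
                "ratio_meth": fit.ratios["alpha_over_p"],
                "ratio_meth_ci68": fit.ratios["alpha_over_p_ci68"],
                "ratio_demeth": fit.ratios["beta_over_q"],
                "ratio_demeth_ci68": fit.ratios["beta_over_q_ci68"],
            }
        )
    if excluded:
        warnings.warn(
            f"excluding non-converged fits: {excluded}", RuntimeWarning, stacklevel=2
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "condition_id",
            "ratio_meth",
            "ratio_meth_ci68",
            "ratio_demeth",
            "ratio_demeth_ci68",
        ],
    )
    summary = {
        "mean_ratio_meth": float(table["ratio_meth"].mean()) if len(table) else np.nan,
        "sd_ratio_meth": float(table["ratio_meth"].std(ddof=1))
        if len(table) > 1
        else np.nan,
        "mean_ratio_demeth": float(table["ratio_demeth"].mean())
        if len(table)
        else np.nan,
        "sd_ratio_demeth": float(table["ratio_demeth"].std(ddof=1))
        if len(table) > 1
        else np.nan,
        "n_conditions": int(len(table)),
        "n_excluded": len(excluded),
        "excluded": excluded,
    }
    return table, summary


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test of two ratio samples.

    W is the first-sample U statistic (count of pairs with x_i > y_j, plus
    1/2 per tied pair) — the convention of R's ``wilcox.test``.  The
    p-value uses exact enumeration when n1*n2 <= 400 and there are no
    ties, and the normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):
        # degenerate: all observations tied, zero-variance normal approximation
        p = 1.0
    return RankSumResult(
        w=float(res.statistic),
        p_value=p,
        n1=int(x.size),
        n2=int(y.size),
        method="exact" if method == "exact" else "normal",
    )
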