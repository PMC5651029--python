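"""Group comparisons mirroring the study's reporting conventions.

Two groups → Student's t-test; three or more → one-way ANOVA followed
by Tukey's honest significant difference post-hoc test.  Summaries are
reported as mean ± SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups"]


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t-test" or "anova"
    statistic: float
    p_value: float
    summary: pd.DataFrame  # group, n, mean, sem
    posthoc: pd.DataFrame | None = None  # Tukey table for > 2 groups


def compare_groups(groups: dict[str, np.ndarray | list[float]],
                   *, alpha: float = 0.05) -> GroupComparison:
    """Compare ≥ 2 groups of values.

    ``groups`` maps group label → per-animal values (each n ≥ 2).
    Zero-variance input is flagged with a warning, not rejected.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {name!r} needs at least two values")
        if np.ptp(a) == 0:
            warnings.warn(f"group {name!r} has zero variance",
                          RuntimeWarning, stacklevel=2)
    summary = pd.DataFrame(
        [(k, a.size, a.mean(), a.std(ddof=1) / np.sqrt(a.size))
         for k, a in arrays.items()],
        columns=["group", "n", "mean", "sem"])

    values = list(arrays.values())
    if len(values) == 2:
        stat, p = sps.ttest_ind(*values)
        return GroupComparison("t-test", float(stat), float(p), summary)

    stat, p = sps.f_oneway(*values)
    res = sps.tukey_hsd(*values)
    names = list(arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            lo, hi = res.confidence_interval(alpha).low[i, j], \
                res.confidence_interval(alpha).high[i, j]
            rows.append((names[i], names[j],
                         arrays[names[i]].mean() - arrays[names[j]].mean(),
                         float(res.pvalue[i, j]), float(lo), float(hi)))
    posthoc = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff",
                                          "p_adj", "ci_low", "ci_high"])
    return GroupComparison("anova", float(stat), float(p), summary, posthoc)
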