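"""Group summaries (mean +/- SEM) and Student's t comparisons.

The unit of analysis is the recording (one CSD wave), not the mouse;
mouse identifiers are carried for transparency only.  Within-specimen
comparisons (baseline vs response area in the same recording) use a
one-tailed paired Student's t-test; between-group comparisons use a
two-tailed two-sample Student's t-test with pooled variance (Welch's
correction available behind a flag).  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "t_paired_one_tailed",
    "t_two_sample_two_tailed",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    sem: float
    n_recordings: int
    n_mice: int | None = None


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    tail: str  # "one" | "two"
    kind: str  # "paired" | "two-sample"


def summarize(
    values: Sequence[float],
    mouse_ids: Sequence[str] | None = None,
    group: str = "",
) -> GroupSummary:
    """Mean and SEM over recordings (SEM = sd / sqrt(n), sd with ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x.size == 1:
        warnings.warn("SEM undefined for a single recording; reporting 0")
        sem = 0.0
    else:
        sem = float(x.std(ddof=1) / np.sqrt(x.size))
    return GroupSummary(
        group=group,
        mean=float(x.mean()),
        sem=sem,
        n_recordings=int(x.size),
        n_mice=len(set(mouse_ids)) if mouse_ids is not None else None,
    )


def t_paired_one_tailed(
    baseline_values: Sequence[float],
    response_values: Sequence[float],
    alternative: str = "greater",
) -> TTestResult:
    """Paired Student's t on response - baseline, one-tailed.

    ``alternative='greater'`` tests response > baseline (swelling);
    ``'less'`` tests response < baseline (constriction).
    """
    a = np.asarray(baseline_values, dtype=float)
    b = np.asarray(response_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    diff = b - a
    if np.all(diff == diff[0]):
        # zero-variance differences: t is undefined; report the limit
        if diff[0] == 0:
            return TTestResult(0.0, a.size - 1, 0.5, "one", "paired")
        warnings.warn(
            "zero-variance nonzero differences; p reported as smallest "
            "representable value"
        )
        right_side = (diff[0] > 0) == (alternative == "greater")
        tiny = float(np.finfo(float).tiny)
        sign = np.sign(diff[0])
        return TTestResult(
            float(sign * np.inf), a.size - 1, tiny if right_side else 1.0 - tiny,
            "one", "paired",
        )
    res = sps.ttest_rel(b, a, alternative=alternative)
    return TTestResult(
        float(res.statistic), float(res.df), float(res.pvalue), "one", "paired"
    )


def t_two_sample_two_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample Student's t (pooled variance), two-tailed.

    Set ``welch=True`` for the unequal-variance correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 recordings")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = float(res.df)
    else:
        df = float(a.size + b.size - 2)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return TTestResult(t, df, p, "two", "two-sample")
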