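"""Group summaries and two-sample comparisons.

Data are summarized as mean +/- SEM with the cell count n; group
comparisons use the unpaired two-tailed t-test (pooled-variance Student
by default, Welch available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .errors import AnalysisError

__all__ = ["SummaryStats", "GroupComparison", "summarize", "t_test_unpaired"]


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sem: float
    n: int
    single: bool = False  # n == 1: sem is 0 by convention


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: SummaryStats
    group_b: SummaryStats
    t_statistic: float
    df: float
    p_value: float
    test: str

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "mean_a": self.group_a.mean, "sem_a": self.group_a.sem, "n_a": self.group_a.n,
            "mean_b": self.group_b.mean, "sem_b": self.group_b.sem, "n_b": self.group_b.n,
            "t": self.t_statistic, "df": self.df, "p": self.p_value, "test": self.test,
        }


def summarize(values) -> SummaryStats:
    """Mean, SEM (sd/sqrt(n), ddof=1) and n of a sample."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise AnalysisError("cannot summarize an empty sample")
    if x.size == 1:
        return SummaryStats(mean=float(x[0]), sem=0.0, n=1, single=True)
    return SummaryStats(mean=float(np.mean(x)),
                        sem=float(np.std(x, ddof=1) / np.sqrt(x.size)),
                        n=int(x.size))


def t_test_unpaired(a, b, welch: bool = False, metric: str = "") -> GroupComparison:
    """Unpaired two-tailed t-test between two samples.

    Pooled-variance Student's t by default; ``welch=True`` uses the
    Welch-Satterthwaite correction.  Degenerate zero-variance groups with
    equal means give t = 0, p = 1 by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("t-test needs at least two values per group")
    sa, sb = summarize(a), summarize(b)
    if np.var(a) == 0 and np.var(b) == 0:
        if sa.mean == sb.mean:
            t, p = 0.0, 1.0
        else:
            t, p = float("-inf") if sa.mean < sb.mean else float("inf"), 0.0
        df = a.size + b.size - 2
    else:
        res = _st.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(metric=metric, group_a=sa, group_b=sb,
                           t_statistic=t, df=df, p_value=p,
                           test="welch_t" if welch else "student_t")
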