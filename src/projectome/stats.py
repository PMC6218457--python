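"""Group summaries (mean ± s.e.m.) and two-sample Student's t comparisons.

The comparison is the classical pooled-variance two-sample two-sided
Student's t-test,

    t = (x̄₁ − x̄₂) / (s_p · sqrt(1/n₁ + 1/n₂)),
    s_p² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2),   df = n₁ + n₂ − 2,

with Welch's unequal-variance variant available behind a flag.  The
s.e.m. is the sample standard deviation (n−1 denominator) over sqrt(n).
Significance stars follow the four-level convention
* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.  No multiple-testing
correction is applied by default; a Benjamini–Hochberg helper is
provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVariance, EmptyGroup

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "sem",
    "summarize_groups",
    "compare_groups",
    "stars",
    "benjamini_hochberg",
]

METRICS = [
    "axonal_length_mm",
    "axonal_branches",
    "axonal_tips",
    "dendritic_length_mm",
    "dendritic_branches",
    "dendritic_tips",
]


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean; NaN for a single value."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / math.sqrt(v.size))


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    means: Dict[str, float]
    sems: Dict[str, float]  # NaN (flagged undefined) when n == 1

    def row(self) -> Dict:
        out: Dict = {"group": self.label, "n": self.n}
        for m in self.means:
            out[f"{m}_mean"] = self.means[m]
            out[f"{m}_sem"] = self.sems[m]
        return out


def summarize_groups(
    records: pd.DataFrame,
    group_col: str = "group",
    metrics: Optional[List[str]] = None,
) -> List[GroupSummary]:
    """Per-group mean and s.e.m. for each metric column.

    ``records`` has one row per neuron, a ``group_col`` label column and
    the metric columns (defaults to the six morphometric summary
    metrics).  Groups are emitted in first-appearance order.
    """
    metrics = metrics or [m for m in METRICS if m in records.columns]
    if group_col not in records.columns:
        raise ValueError(f"missing group column {group_col!r}")
    out = []
    for label in records[group_col].drop_duplicates():
        sub = records[records[group_col] == label]
        if len(sub) == 0:
            raise EmptyGroup(label)
        out.append(
            GroupSummary(
                label=str(label),
                n=len(sub),
                means={m: float(sub[m].mean()) for m in metrics},
                sems={m: sem(sub[m].to_numpy()) for m in metrics},
            )
        )
    return out


def stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    significance: str
    welch: bool = False


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    labels: Tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> ComparisonResult:
    """Two-sample two-sided Student's t-test (pooled variance by default).

    Raises :class:`DegenerateVariance` when the (pooled) variance is zero
    — both samples constant — leaving t infinite or undefined.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if welch:
        denom2 = v1 / n1 + v2 / n2
        if denom2 == 0.0:
            raise DegenerateVariance("both samples are constant")
        t = (x.mean() - y.mean()) / math.sqrt(denom2)
        df = denom2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0.0:
            raise DegenerateVariance("pooled variance is zero")
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return ComparisonResult(
        metric=metric,
        group_a=labels[0],
        group_b=labels[1],
        t=float(t),
        df=float(df),
        p=p,
        significance=stars(p),
        welch=welch,
    )


def compare_group_table(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = "group",
    metrics: Optional[List[str]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Metric-by-metric comparison of two labeled groups as a DataFrame."""
    metrics = metrics or [m for m in METRICS if m in records.columns]
    rows = []
    for m in metrics:
        x = records.loc[records[group_col] == group_a, m].to_numpy()
        y = records.loc[records[group_col] == group_b, m].to_numpy()
        try:
            r = compare_groups(x, y, metric=m, labels=(group_a, group_b), welch=welch)
            rows.append(
                {
                    "metric": m,
                    "group_a": group_a,
                    "group_b": group_b,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "significance": r.significance,
                }
            )
        except DegenerateVariance:
            rows.append(
                {
                    "metric": m,
                    "group_a": group_a,
                    "group_b": group_b,
                    "t": float("nan"),
                    "df": float("nan"),
                    "p": float("nan"),
                    "significance": "degenerate",
                }
            )
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
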