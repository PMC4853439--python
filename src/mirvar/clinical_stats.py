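"""Group- and genotype-stratified comparisons of continuous phenotypes.

Two-sample t tests (pooled-variance Student by default, Welch optional),
paired t on differences, one-way ANOVA with Sidak-adjusted pairwise
comparisons on the pooled within-group mean square, and mean +/- SEM group
summaries. All tests are two-sided; missing values are dropped per comparison
with counts logged.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "two_sample_t",
    "paired_t",
    "anova_sidak",
    "group_summary",
    "sidak_adjust",
]

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Raised when a test statistic is undefined because variance is zero."""


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Per-group n, mean and SEM (sd/sqrt(n); missing when n = 1)."""

    labels: tuple[str, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sem: tuple[float | None, ...]


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str
    adjusted_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "method": self.method,
        }


def _clean(values: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[np.isfinite(arr)]
    dropped = len(list(values)) - len(arr)
    if dropped:
        logger.info("dropped %d missing/non-finite value(s) from %s", dropped, label)
    return arr


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: str = "student"
) -> ComparisonResult:
    """Unpaired two-sample t test, two-sided.

    ``variant='student'`` pools the variance (df = n1 + n2 - 2);
    ``variant='welch'`` uses the Satterthwaite approximation.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    x, y = _clean(x, "x"), _clean(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    equal_var = variant == "student"
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() != y.mean():
        raise ZeroVarianceError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    df = len(x) + len(y) - 2 if equal_var else float(res.df)
    return ComparisonResult(float(res.statistic), float(df), float(res.pvalue), variant)


def paired_t(d: Sequence[float]) -> ComparisonResult:
    """Paired t test on pre-computed differences: t = mean(d)/(sd(d)/sqrt(n))."""
    d = _clean(d, "differences")
    if len(d) < 2:
        raise ValueError("need >= 2 pairs")
    if d.std(ddof=1) == 0:
        raise ZeroVarianceError("all differences identical")
    res = stats.ttest_1samp(d, 0.0)
    return ComparisonResult(float(res.statistic), float(len(d) - 1), float(res.pvalue), "paired_t")


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m over m comparisons."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("need p in [0,1] and m >= 1")
    return float(1 - (1 - p) ** m)


def anova_sidak(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] = (),
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA plus Sidak-adjusted pairwise comparisons.

    The omnibus F uses the usual between/within decomposition. Each requested
    pair is tested with a t statistic on the pooled within-group mean square
    (df = N - k), then Sidak-adjusted over the m requested comparisons — the
    family is the explicit comparison list, not all pairs.
    """
    cleaned = {k: _clean(v, k) for k, v in groups.items()}
    if len(cleaned) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) < 2 for v in cleaned.values()):
        raise ValueError("each group needs n >= 2")
    arrays = list(cleaned.values())
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    ms_within = sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / (n_total - k)
    means = {g: a.mean() for g, a in cleaned.items()}
    if ms_within == 0:
        if len(set(means.values())) > 1:
            raise ZeroVarianceError("zero within-group variance with unequal means")
        omnibus = ComparisonResult(0.0, (float(k - 1), float(n_total - k)), 1.0, "anova")
    else:
        f, p = stats.f_oneway(*arrays)
        omnibus = ComparisonResult(
            float(f), (float(k - 1), float(n_total - k)), float(p), "anova"
        )

    m = len(comparisons)
    pairwise = []
    for g1, g2 in comparisons:
        n1, n2 = len(cleaned[g1]), len(cleaned[g2])
        se = math.sqrt(ms_within * (1 / n1 + 1 / n2))
        if se == 0:
            raise ZeroVarianceError(f"zero pooled variance for pair ({g1}, {g2})")
        t = (means[g1] - means[g2]) / se
        df = n_total - k
        p = 2 * stats.t.sf(abs(t), df)
        pairwise.append(
            ComparisonResult(
                float(t), float(df), float(p), f"pooled_t:{g1}-vs-{g2}",
                adjusted_p=sidak_adjust(float(p), m),
            )
        )
    return omnibus, pairwise


def group_summary(groups: Mapping[str, Sequence[float]]) -> GroupSummary:
    """Mean and SEM per group; SEM is None at n = 1 (sd undefined)."""
    labels, ns, means, sems = [], [], [], []
    for label, values in groups.items():
        arr = _clean(values, label)
        if len(arr) == 0:
            raise ValueError(f"group {label!r} is empty after dropping missing values")
        labels.append(label)
        ns.append(len(arr))
        means.append(float(arr.mean()))
        sems.append(None if len(arr) == 1 else float(arr.std(ddof=1) / math.sqrt(len(arr))))
    return GroupSummary(tuple(labels), tuple(ns), tuple(means), tuple(sems))
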