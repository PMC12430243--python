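"""Method-validation statistics: replicate precision and pairwise t-tests.

Precision is summarised per replicate set as SD (n-1 denominator), RSD
(100·SD/mean) and — when a nominal spiked amount is known — recovery
(100·mean/nominal).  Method/signal combinations are compared pairwise with
Welch's unequal-variance two-sided t-test; replicate counts of 8-10 and
visibly unequal variances across detectors make the pooled-variance
assumption unsafe, though the pooled variant is available behind a flag.
No multiple-testing correction is applied across a comparison matrix; the
number of significant flags is reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateSet",
    "ValidationStats",
    "TTestResult",
    "ComparisonMatrix",
    "summarize",
    "compare",
    "comparison_matrix",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate determinations (µmol or content units) under one label."""

    values: Sequence[float]
    nominal: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def n(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class ValidationStats:
    mean: float
    sd: float
    rsd_percent: float
    recovery_percent: Optional[float] = None
    n: int = 0


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    degenerate: bool = False  # zero variance in both sets

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def summarize(replicates: ReplicateSet) -> ValidationStats:
    """Mean, sample SD, RSD% and (if a nominal is given) recovery%."""
    if replicates.n < 2:
        raise ValueError("dispersion statistics require at least 2 replicates")
    x = replicates.as_array()
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        raise ValueError("RSD undefined for zero mean")
    rsd = 100.0 * sd / mean
    recovery = (
        100.0 * mean / replicates.nominal if replicates.nominal is not None else None
    )
    return ValidationStats(
        mean=mean, sd=sd, rsd_percent=rsd, recovery_percent=recovery, n=replicates.n
    )


def compare(a: ReplicateSet, b: ReplicateSet, *, pooled: bool = False) -> TTestResult:
    """Two-sided two-sample t-test (Welch by default, pooled on request).

    Degenerate zero-variance inputs are resolved by convention: both sets
    constant with equal means -> p = 1; constant with different means ->
    p = 0 (flagged).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("t-test requires at least 2 replicates per set")
    xa, xb = a.as_array(), b.as_array()
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        equal = xa.mean() == xb.mean()
        return TTestResult(
            statistic=0.0 if equal else np.inf,
            df=float(a.n + b.n - 2),
            p_value=1.0 if equal else 0.0,
            degenerate=True,
        )
    res = stats.ttest_ind(xa, xb, equal_var=pooled)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class ComparisonMatrix:
    """Symmetric pairwise p-value table with 0.05 significance flags."""

    p_values: pd.DataFrame  # NaN on the diagonal
    significant: pd.DataFrame  # boolean, False on the diagonal
    n_significant_pairs: int
    alpha: float = 0.05

    def to_csv_frame(self) -> pd.DataFrame:
        """Render for CSV output with '-' on the diagonal."""
        out = self.p_values.round(4).astype(object)
        for lbl in out.index:
            out.loc[lbl, lbl] = "-"
        return out


def comparison_matrix(
    sets: Sequence[ReplicateSet], *, alpha: float = 0.05, pooled: bool = False
) -> ComparisonMatrix:
    """All pairwise two-sided p-values across labelled replicate sets."""
    if len(sets) < 2:
        raise ValueError("comparison matrix requires at least 2 sets")
    labels: List[str] = []
    for i, s in enumerate(sets):
        labels.append(s.label or f"set{i}")
    if len(set(labels)) != len(labels):
        raise ValueError("replicate-set labels must be unique")
    n = len(sets)
    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            pij = compare(sets[i], sets[j], pooled=pooled).p_value
            p[i, j] = p[j, i] = pij
    pdf = pd.DataFrame(p, index=labels, columns=labels)
    sig = (pdf < alpha).fillna(False)
    n_sig = int(sig.to_numpy()[np.triu_indices(n, k=1)].sum())
    return ComparisonMatrix(
        p_values=pdf, significant=sig, n_significant_pairs=n_sig, alpha=alpha
    )
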