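"""Statistical tests used across the analyses.

Mann-Whitney U (two-sided; exact for small tie-free samples, normal
approximation with tie and continuity correction otherwise) and the
two-sample proportion test in the form R's ``prop.test`` uses
(chi-square with Yates continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 16  # n1 + n2 at or below this (tie-free) -> exact enumeration


@dataclass
class StatResult:
    u: float
    p: float
    n1: int
    n2: int
    direction: str  # which sample is larger by median: 'x', 'y' or 'none'

    def __post_init__(self) -> None:
        if not (0 <= self.u <= self.n1 * self.n2):
            raise ValueError("U out of range")
        if not (0 < self.p <= 1):
            raise ValueError("P out of range")


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when n1 + n2 <= 16 and the pooled sample has
    no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    mx, my = float(np.median(x)), float(np.median(y))
    direction = "x" if mx > my else ("y" if my > mx else "none")
    return StatResult(
        u=float(res.statistic),
        p=min(1.0, float(res.pvalue)),
        n1=int(x.size),
        n2=int(y.size),
        direction=direction,
    )


@dataclass
class PropTestResult:
    prop1: float
    prop2: float
    statistic: float
    p: float
    direction: str  # 'first', 'second' or 'none'


def two_sample_proportion_test(
    count1: int, n1: int, count2: int, n2: int
) -> PropTestResult:
    """Two-sample test of equal proportions with continuity correction
    (the prop.test form)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array(
        [[count1, n1 - count1], [count2, n2 - count2]], dtype=float
    )
    p1, p2 = count1 / n1, count2 / n2
    if table.min() < 0:
        raise ValueError("counts cannot exceed group sizes")
    # degenerate margins (all successes or all failures) -> no evidence
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return PropTestResult(p1, p2, 0.0, 1.0, "none")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    direction = "first" if p1 > p2 else ("second" if p2 > p1 else "none")
    return PropTestResult(p1, p2, float(chi2), min(1.0, float(p)), direction)
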