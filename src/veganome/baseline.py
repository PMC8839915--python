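"""Baseline-characteristics ("Table 1") statistics.

Continuous variables are compared with the Welch unequal-variance
two-sample t-test computed directly from per-group summary statistics
(mean, SD, n), so a published table can be re-checked from its printed
cells.  Binary variables use the Yates continuity-corrected chi-square
on the 2×2 counts — the correction matters at these sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NONVEG, VEGAN, CohortMetadata

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """Per-group summary: mean/sd/n for continuous, count/total for categorical."""

    n: int
    mean: float | None = None
    sd: float | None = None
    count: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.count is not None and self.count > self.n:
            raise ValueError("count cannot exceed n")


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Welch t, Welch–Satterthwaite df and two-sided p from group summaries."""
    for g in (g1, g2):
        if g.n < 2:
            raise ValueError("each group needs n >= 2")
        if g.mean is None or g.sd is None:
            raise ValueError("continuous summaries require mean and sd")
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    if v1 + v2 == 0:
        if g1.mean == g2.mean:
            logger.info("zero variance in both groups with equal means; p = 1")
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (g2.mean - g1.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Continuity-corrected chi-square for the 2×2 table [[a, b], [c, d]].

    χ² = n(|ad − bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in the 2×2 table; use an exact test")
    num = n * (max(abs(a * d - b * c) - n / 2.0, 0.0)) ** 2
    chi2 = num / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), 1, p


def baseline_table(
    metadata: CohortMetadata,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
) -> pd.DataFrame:
    """Table-1-style summary of a metadata table, by diet group.

    Continuous columns are summarised as mean (SD) with Welch p-values;
    binary (0/1) columns as count (%) with Yates chi-square p-values.
    """
    tab = metadata.table
    if continuous is None:
        continuous = [
            c for c in tab.columns
            if c != "diet" and tab[c].dropna().nunique() > 2
        ]
    if binary is None:
        binary = [
            c for c in tab.columns
            if c != "diet" and 1 <= tab[c].dropna().nunique() <= 2
        ]
    g_non = tab[tab["diet"] == NONVEG]
    g_veg = tab[tab["diet"] == VEGAN]
    rows = []
    for col in continuous:
        x1, x2 = g_non[col].dropna(), g_veg[col].dropna()
        t, df, p = welch_t_from_summary(
            GroupSummary(n=len(x1), mean=x1.mean(), sd=x1.std(ddof=1)),
            GroupSummary(n=len(x2), mean=x2.mean(), sd=x2.std(ddof=1)),
        )
        rows.append(
            {"variable": col, "type": "continuous",
             "nonveg": f"{x1.mean():.1f} ({x1.std(ddof=1):.1f})",
             "vegan": f"{x2.mean():.1f} ({x2.std(ddof=1):.1f})",
             "statistic": t, "p_value": p}
        )
    for col in binary:
        x1, x2 = g_non[col].dropna(), g_veg[col].dropna()
        a, b = int(x1.sum()), int(len(x1) - x1.sum())
        c, d = int(x2.sum()), int(len(x2) - x2.sum())
        try:
            chi2, _, p = yates_chi_square(a, b, c, d)
        except ValueError:
            chi2, p = np.nan, np.nan
        rows.append(
            {"variable": col, "type": "binary",
             "nonveg": f"{a} ({100 * a / max(len(x1), 1):.1f})",
             "vegan": f"{c} ({100 * c / max(len(x2), 1):.1f})",
             "statistic": chi2, "p_value": p}
        )
    return pd.DataFrame(rows).set_index("variable")
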