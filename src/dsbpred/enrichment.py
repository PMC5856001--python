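"""Colocalization enrichment: percentages, odds ratios, Fisher tests, FDR.

A feature's association with DSB sites is summarised by a 2x2 table of
(class x feature presence). The odds ratio is (a*d)/(b*c); a logistic
coefficient beta maps to the same scale as exp(beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "colocalization",
    "odds_ratio",
    "odds_ratio_from_percentages",
    "enrichment_test",
    "adjust_pvalues",
    "beta_to_or",
    "enrichment_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = positives with feature, b = positives without,
    c = negatives with feature, d = negatives without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell, val in zip("abcd", (self.a, self.b, self.c, self.d)):
            if val < 0 or val != int(val):
                raise ValueError(f"cell {cell} must be a non-negative integer, got {val}")

    @property
    def n_pos(self) -> int:
        return self.a + self.b

    @property
    def n_neg(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def colocalization(table: ContingencyTable2x2) -> tuple[float, float]:
    """Percent of positives and of negatives carrying the feature."""
    if table.n_pos == 0 or table.n_neg == 0:
        raise ValueError("both classes must be non-empty")
    return 100.0 * table.a / table.n_pos, 100.0 * table.c / table.n_neg


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> float:
    """(a*d)/(b*c); with ``haldane`` 0.5 is added to every cell first.

    Without the correction a zero denominator yields ``inf`` (or 0.0 when the
    numerator is zero too) rather than raising — degenerate tables surface as
    explicit flags, never as silently shifted estimates.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    num, den = a * d, b * c
    if den == 0:
        return 0.0 if num == 0 else math.inf
    return num / den


def odds_ratio_from_percentages(pct_pos: float, pct_neg: float) -> float:
    """OR implied by the two colocalization percentages:
    (p1/(100-p1)) / (p0/(100-p0))."""
    if not (0 < pct_pos < 100) or not (0 < pct_neg < 100):
        raise ValueError("percentages must lie strictly between 0 and 100")
    return (pct_pos / (100 - pct_pos)) / (pct_neg / (100 - pct_neg))


def enrichment_test(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for the 2x2 association."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' (min(1, m*p)) or 'BH' step-up."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}.get(
        method.lower()
    )
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def beta_to_or(beta: float) -> float:
    """Odds ratio implied by a logistic regression coefficient: exp(beta)."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    return math.exp(beta)


def enrichment_report(
    presence_pos: pd.DataFrame,
    presence_neg: pd.DataFrame,
    correction: str = "bonferroni",
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-feature enrichment table from boolean presence matrices.

    ``presence_pos`` / ``presence_neg`` are sites x features boolean (or
    0/1) frames with identical columns; a site is feature-positive if its
    entry is truthy (for motif counts: count >= 1). The report carries
    pct_pos, pct_neg, odds_ratio, p_raw and p_adj, sorted by odds ratio
    descending.
    """
    if list(presence_pos.columns) != list(presence_neg.columns):
        raise ValueError("presence matrices must share identical feature columns")
    rows = []
    for feat in presence_pos.columns:
        a = int(presence_pos[feat].astype(bool).sum())
        b = len(presence_pos) - a
        c = int(presence_neg[feat].astype(bool).sum())
        d = len(presence_neg) - c
        t = ContingencyTable2x2(a, b, c, d)
        pct_pos, pct_neg = colocalization(t)
        rows.append(
            {
                "feature": feat,
                "pct_pos": pct_pos,
                "pct_neg": pct_neg,
                "odds_ratio": odds_ratio(t, haldane=haldane),
                "p_raw": enrichment_test(t),
            }
        )
    report = pd.DataFrame(rows).set_index("feature")
    report["p_adj"] = adjust_pvalues(report["p_raw"].to_numpy(), correction)
    report["correction"] = correction
    return report.sort_values("odds_ratio", ascending=False)
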