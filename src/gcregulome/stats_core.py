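"""Exact and asymptotic statistics shared by every pipeline stage.

Thin, validated wrappers: Fisher's exact test (probability-mass two-sided
rule), two-sample Kolmogorov-Smirnov with the asymptotic null, the
Benjamini-Hochberg step-up, and a stable binomial upper tail. The heavy
lifting is delegated to scipy/statsmodels; the wrappers pin down the exact
conventions the rest of the package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are the exposure, columns the outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("all margins are zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(
    table: ContingencyTable2x2, sided: str = "two"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p). The odds ratio is the sample odds ratio
    a*d / (b*c): infinity when b*c == 0 with a*d > 0, NaN when both
    products vanish. The two-sided p sums hypergeometric probabilities of
    all tables with fixed margins whose probability does not exceed the
    observed table's (the probability-mass rule).
    """
    if sided not in {"two", "greater"}:
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    arr = table.as_array()
    alternative = "two-sided" if sided == "two" else "greater"
    res = stats.fisher_exact(arr, alternative=alternative)
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    return float(odds), float(res.pvalue)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic Kolmogorov p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to 1.

    q preserves the ordering of p (monotone non-decreasing in p).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_upper_tail(x: int, n: int, p0: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p0), computed via the survival function."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly in (0, 1)")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p0))


def binomial_upper_tail_vec(x, n, p0) -> np.ndarray:
    """Vectorised ``binomial_upper_tail`` (no per-element validation short of broadcast)."""
    x = np.asarray(x)
    p = stats.binom.sf(x - 1, n, p0)
    return np.where(x <= 0, 1.0, p)
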