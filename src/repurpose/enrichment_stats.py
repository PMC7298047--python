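"""2x2 contingency statistics for target-set and cohort comparisons.

Three primitives live here: the chi-squared test with optional Yates
continuity correction, the two-sided Fisher exact test, and
Benjamini-Hochberg step-up FDR adjustment.

The chi-squared statistic uses the 2x2 shortcut form

    X^2 = n * (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d))

where the ``n/2`` term is the continuity correction (dropped when the
correction is off) and the corrected difference is clamped at zero when
``|ad - bc| <= n/2``.  Cells may be real-valued: the pharmaco-epidemiology
screen rescales small cohorts to a pseudo-cohort of fixed size, which
produces fractional event counts.  The Fisher exact test, by contrast,
requires integer cells.

P-values are never reported as exactly zero; underflow is floored at the
smallest positive normal double and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["ContingencyTable", "TestResult", "chi_squared", "fisher_exact", "bh_fdr"]

logger = logging.getLogger(__name__)

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table of nonnegative (possibly real-valued) counts.

    Row 1 is the group of interest (event, non-event); row 2 the
    reference group (event, non-event).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(not math.isfinite(x) for x in cells):
            raise ValueError(f"non-finite cell in contingency table: {cells}")
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in contingency table: {cells}")
        if self.n <= 0:
            raise ValueError("contingency table total must be positive")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[float, float, float, float]:
        """(row1, row2, col1, col2) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def is_integer(self) -> bool:
        return all(float(x).is_integer() for x in (self.a, self.b, self.c, self.d))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a 2x2 test: statistic (None for exact tests), p, method."""

    statistic: float | None
    p_value: float
    method: str


def _floor_p(p: float, context: str) -> float:
    if p <= 0.0:
        logger.warning("p-value underflow in %s; flooring at %.3e", context, _P_FLOOR)
        return _P_FLOOR
    return min(p, 1.0)


def chi_squared(table: ContingencyTable, continuity_correction: bool = True) -> TestResult:
    """Chi-squared test on a 2x2 table (1 degree of freedom).

    Parameters
    ----------
    table
        The 2x2 counts; real-valued cells are permitted.
    continuity_correction
        Apply the Yates correction (subtract ``n/2`` from ``|ad - bc|``,
        clamping at zero).

    Raises
    ------
    ValueError
        If any marginal total is zero ("degenerate margin"); callers may
        fall back to :func:`fisher_exact`.
    """
    if any(m <= 0 for m in table.margins):
        raise ValueError(f"degenerate margin in contingency table {table}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    r1, r2, c1, c2 = table.margins
    statistic = n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    method = "chi2_yates" if continuity_correction else "chi2"
    return TestResult(statistic=statistic, p_value=_floor_p(p, method), method=method)


def _hypergeom_log_pmf(k: np.ndarray, n: int, K: int, size: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(n, K, size)."""

    def _logcomb(N: float, r: np.ndarray) -> np.ndarray:
        return gammaln(N + 1) - gammaln(r + 1) - gammaln(N - r + 1)

    return _logcomb(K, k) + _logcomb(n - K, size - k) - _logcomb(n, size)


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table with integer cells.

    The two-sided p-value sums the hypergeometric probabilities, over all
    tables sharing the observed margins, of outcomes no more probable
    than the observed one.
    """
    if not table.is_integer():
        raise ValueError("exact test requires integer counts")
    a = int(table.a)
    r1, r2, c1, c2 = (int(m) for m in table.margins)
    n = int(table.n)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    if len(support) == 1:
        return TestResult(statistic=None, p_value=1.0, method="fisher")
    log_pmf = _hypergeom_log_pmf(support, n, c1, r1)
    log_obs = log_pmf[a - lo]
    # relative tolerance guards against ties broken by rounding
    mask = log_pmf <= log_obs + 1e-9
    p = float(np.exp(logsumexp(log_pmf[mask])))
    return TestResult(statistic=None, p_value=_floor_p(p, "fisher"), method="fisher")


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    One-sided overrepresentation probability used by enrichment scoring.
    """
    return _floor_p(float(stats.hypergeom.sf(k - 1, N, K, n)), "hypergeom_sf")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns q-values in the input order: ``q(i) = min_{j >= i} p(j)*m/j``
    over the sorted p-values, clamped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
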