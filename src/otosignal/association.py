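"""Contingency-table tests for differences in event counts between strata.

Each adverse-event group is tested across the levels of one stratum axis
with an r x 2 table of (event reports, stratum population minus event
reports), built against the external vaccinated-population denominators.
Pearson's chi-squared test (no continuity correction) is used unless the
table is 2 x 2 with an expected cell below 5, in which case Fisher's exact
test applies (the Cochran criterion). All tests are two-sided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateTableError, UnsupportedShapeError

log = logging.getLogger(__name__)

#: Relative tie tolerance when summing hypergeometric outcomes as extreme as
#: the observed one (matches the convention of R's fisher.test).
_FISHER_TIE_EPS = 1e-7


class TestMethod(str, Enum):
    CHI_SQUARED = "CHI_SQUARED"
    FISHER_EXACT = "FISHER_EXACT"


@dataclass(frozen=True)
class ContingencyTable:
    """An r x 2 grid: per stratum level, event count vs non-event count.

    Row sums are the stratum sample sizes. Stored as int64 because
    population denominators dwarf event counts.
    """

    cells: np.ndarray

    def __init__(self, cells):
        arr = np.asarray(cells, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
            raise UnsupportedShapeError(f"expected an r x 2 table with r >= 2, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("contingency cells must be non-negative")
        object.__setattr__(self, "cells", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def expected(self) -> np.ndarray:
        rows = self.cells.sum(axis=1, keepdims=True)
        cols = self.cells.sum(axis=0, keepdims=True)
        total = self.cells.sum()
        if total == 0:
            raise DegenerateTableError("empty contingency table")
        return rows * cols / total


@dataclass(frozen=True)
class TestResult:
    method: TestMethod
    statistic: float | None
    df: int | None
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def choose_method(table: ContingencyTable) -> TestMethod:
    """Fisher's exact test for 2 x 2 tables with any expected cell < 5, else chi-squared."""
    try:
        small = bool((table.expected() < 5).any())
    except DegenerateTableError:
        small = True
    if small and table.shape == (2, 2):
        return TestMethod.FISHER_EXACT
    if small:
        log.warning(
            "r x 2 table with expected cells < 5; chi-squared approximation may be poor"
        )
    return TestMethod.CHI_SQUARED


def chi_squared(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared without continuity correction."""
    cells = table.cells
    if (cells.sum(axis=1) == 0).any() or (cells.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(cells, correction=False)
    return TestResult(TestMethod.CHI_SQUARED, float(stat), int(df), float(p))


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test on a 2 x 2 table.

    The p-value sums, over the hypergeometric support fixed by the observed
    margins, the probabilities of all tables no more likely than the
    observed one.
    """
    if table.shape != (2, 2):
        raise UnsupportedShapeError(f"Fisher's exact test needs a 2 x 2 table, got {table.shape}")
    a = int(table.cells[0, 0])
    r1 = int(table.cells[0].sum())
    c1 = int(table.cells[:, 0].sum())
    n = int(table.cells.sum())
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        # a degenerate margin admits a single table: p = 1
        return TestResult(TestMethod.FISHER_EXACT, None, None, 1.0)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = _hypergeom_pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_EPS)].sum())
    return TestResult(TestMethod.FISHER_EXACT, None, None, min(p, 1.0))


def _hypergeom_pmf(k: np.ndarray, n: int, successes: int, draws: int) -> np.ndarray:
    """Hypergeometric pmf over ``k`` via log-gamma (fast for whole supports)."""

    def lchoose(top, bottom):
        return gammaln(top + 1) - gammaln(bottom + 1) - gammaln(top - bottom + 1)

    logp = (
        lchoose(successes, k)
        + lchoose(n - successes, draws - k)
        - lchoose(n, draws)
    )
    return np.exp(logp)


def apply_test(table: ContingencyTable) -> TestResult:
    """Apply the selection rule and run the chosen test."""
    method = choose_method(table)
    if method == TestMethod.FISHER_EXACT:
        return fisher_exact(table)
    return chi_squared(table)


def stratum_event_table(
    event_counts: Sequence[int], sample_sizes: Sequence[int]
) -> ContingencyTable:
    """Build the r x 2 event/non-event table from per-stratum counts and populations."""
    events = np.asarray(event_counts, dtype=np.int64)
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    if events.shape != sizes.shape:
        raise ValueError("event counts and sample sizes must align")
    if (events > sizes).any():
        raise ValueError("event count exceeds its stratum sample size")
    return ContingencyTable(np.column_stack([events, sizes - events]))
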