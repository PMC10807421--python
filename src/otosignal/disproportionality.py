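"""Proportional reporting ratio (PRR) signal detection.

For an adverse-event group, with

* ``m`` — reports of the event for the index vaccine,
* ``n`` — total reports for the index vaccine,
* ``M`` — reports of the event across the entire reporting database,
* ``N`` — total reports across the entire database,

the PRR is the ratio of reporting proportions

    PRR = (m / n) / ((M - m) / (N - n)),

i.e. the event's share among index-vaccine reports over its share among all
other reports. Its confidence interval is the standard log-normal
(delta-method) interval

    exp( ln PRR  +/-  z_{1-alpha/2} * sqrt(1/m - 1/n + 1/(M-m) - 1/(N-n)) ).

A PRR at or above 2 conventionally flags a signal; the classical auxiliary
criteria (m >= 3 and chi-squared >= 4) are available but off by default.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

from scipy import stats

from .errors import BackgroundZeroError, ConfigurationError
from .models import ANY_GROUP, GroupCounts

log = logging.getLogger(__name__)

DEFAULT_SIGNAL_THRESHOLD = 2.0


def _check_mnMN(m: int, n: int, M: int, N: int) -> None:
    if not (0 <= m <= n and m <= M <= N and n <= N):
        raise ValueError(f"inconsistent counts m={m}, n={n}, M={M}, N={N}")
    if n == 0:
        raise ValueError("index corpus is empty (n = 0)")
    if N - n == 0:
        raise BackgroundZeroError("background corpus is empty (N - n = 0)")


def prr(m: int, n: int, M: int, N: int, continuity: bool = False) -> float:
    """Point estimate of the proportional reporting ratio.

    ``m = 0`` returns 0.0 (with a log note); a zero background cell
    ``M - m = 0`` raises BackgroundZeroError unless ``continuity`` is set,
    which adds 0.5 to each of the four derived cells.
    """
    _check_mnMN(m, n, M, N)
    if continuity:
        a, b = m + 0.5, (n - m) + 0.5
        c, d = (M - m) + 0.5, (N - n) - (M - m) + 0.5
        return (a / (a + b)) / (c / (c + d))
    if m == 0:
        log.info("PRR numerator m = 0; returning 0")
        return 0.0
    if M - m == 0:
        raise BackgroundZeroError(
            f"event absent from background (M - m = 0, m={m}); "
            "enable the continuity correction to proceed"
        )
    return (m / n) / ((M - m) / (N - n))


def prr_se_log(m: int, n: int, M: int, N: int) -> float:
    """Delta-method standard error of ln PRR."""
    if m < 1 or M - m < 1:
        raise ValueError("SE of ln PRR needs m >= 1 and M - m >= 1")
    var = 1.0 / m - 1.0 / n + 1.0 / (M - m) - 1.0 / (N - n)
    return math.sqrt(max(var, 0.0))


def prr_ci(
    m: int, n: int, M: int, N: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided log-normal confidence interval for the PRR.

    Undefined (NaN, NaN) when m = 0 or the event is absent from the
    background.
    """
    _check_mnMN(m, n, M, N)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m == 0 or M - m == 0:
        log.info("PRR CI undefined for m=%d, M-m=%d", m, M - m)
        return (math.nan, math.nan)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    centre = math.log(prr(m, n, M, N))
    half = z * prr_se_log(m, n, M, N)
    return (math.exp(centre - half), math.exp(centre + half))


@dataclass(frozen=True)
class PRRResult:
    """PRR point estimate, interval and signal flag for one event group."""

    group: str
    m: int
    n: int
    M: int
    N: int
    prr: float
    se_log: float
    ci_low: float
    ci_high: float
    signal: bool

    def __post_init__(self):
        if not (math.isnan(self.ci_low) or self.ci_low <= self.prr <= self.ci_high):
            raise ValueError(
                f"{self.group}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket PRR {self.prr}"
            )


def prr_result(
    group: str,
    m: int,
    n: int,
    M: int,
    N: int,
    threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    alpha: float = 0.05,
    continuity: bool = False,
    auxiliary_criteria: bool = False,
) -> PRRResult:
    """Assemble a PRRResult, applying the signal rule.

    With ``auxiliary_criteria`` the classical m >= 3 and chi-squared >= 4
    conditions are required in addition to the bare threshold.
    """
    estimate = prr(m, n, M, N, continuity=continuity)
    if continuity:
        # interval from the same corrected cells, so it brackets the estimate
        mf, nf = m + 0.5, n + 1.0
        cf, df = (M - m) + 0.5, (N - n) + 1.0
        se = math.sqrt(max(1 / mf - 1 / nf + 1 / cf - 1 / df, 0.0))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        low, high = (
            math.exp(math.log(estimate) - z * se),
            math.exp(math.log(estimate) + z * se),
        )
    elif m >= 1 and M - m >= 1:
        se = prr_se_log(m, n, M, N)
        low, high = prr_ci(m, n, M, N, alpha=alpha)
    else:
        se, low, high = math.nan, math.nan, math.nan
    signal = estimate >= threshold
    if signal and auxiliary_criteria:
        signal = m >= 3 and _prr_chi2(m, n, M, N) >= 4.0
    return PRRResult(
        group=group, m=m, n=n, M=M, N=N,
        prr=estimate, se_log=se, ci_low=low, ci_high=high, signal=signal,
    )


def _prr_chi2(m: int, n: int, M: int, N: int) -> float:
    """Pearson chi-squared (no correction) of the 2 x 2 reporting table."""
    a, b = m, n - m
    c, d = M - m, (N - n) - (M - m)
    total = a + b + c + d
    num = total * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den if den else 0.0


def prr_table(
    index: GroupCounts,
    background: GroupCounts,
    threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    alpha: float = 0.05,
    continuity: bool = False,
    auxiliary_criteria: bool = False,
) -> list[PRRResult]:
    """PRR results for every event group of the index corpus.

    ``index`` holds per-group report counts (m) and the index total (n);
    ``background`` holds the same for all *other* reports, so M = m +
    background count and N = n + background total. The pseudo-group ANY is
    excluded. Groups reported for the index vaccine but absent from the
    background have no finite PRR; with the continuity correction off they
    are skipped with a warning rather than failing the whole table.
    Results are sorted by group name.
    """
    if background.total_reports == 0:
        raise ConfigurationError("PRR needs a non-empty background corpus")
    n = index.total_reports
    N = n + background.total_reports
    results = []
    for group in sorted(set(index.counts) | set(background.counts)):
        if group == ANY_GROUP:
            continue
        m = index.counts.get(group, 0)
        M = m + background.counts.get(group, 0)
        try:
            results.append(
                prr_result(
                    group, m, n, M, N,
                    threshold=threshold, alpha=alpha,
                    continuity=continuity, auxiliary_criteria=auxiliary_criteria,
                )
            )
        except BackgroundZeroError:
            log.warning(
                "group %r: event absent from background (m=%d); skipped "
                "(enable the continuity correction to include it)", group, m,
            )
    return results
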