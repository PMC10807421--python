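"""Stratified report counts, percentage shares and crude incidence rates.

Incidence here is crude reports per 100,000 vaccinated persons:
``IR = count / denominator x 1e5`` against an external population
denominator, computed per adverse-event group within each stratum of an
axis (sex, age band, or vaccine manufacturer). The percentage share of a
group is taken against the stratum's total otolaryngologic report count
(the "Any" row), so shares are column-wise and need not sum to 100 across
groups when reports map to several groups.

Internal arithmetic is full precision; display rounding (3 decimals for
IRs, 2 for shares, half-even) happens only on write.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDenominatorError, UndefinedShareError
from .models import (
    ALL_LEVEL,
    ANY_GROUP,
    DenominatorTable,
    DoseSeries,
    GroupedReport,
    Manufacturer,
    Sex,
    StratumAxis,
)

log = logging.getLogger(__name__)

PER = 100_000.0

#: Fixed level ordering per axis (manufacturer levels are restricted further
#: by denominator availability at table-build time).
AXIS_LEVELS: dict[StratumAxis, tuple[str, ...]] = {
    StratumAxis.TOTAL: (ALL_LEVEL,),
    StratumAxis.SEX: ("M", "F"),
    StratumAxis.AGE: ("0-17", "18-49", "50-64", "65+"),
    StratumAxis.MANUFACTURER: ("PFIZER_BIONTECH", "MODERNA", "JANSSEN"),
}


def incidence_rate(count: int, denominator: int) -> float:
    """Crude rate per 100,000 persons.

    Raises MissingDenominatorError-compatible ValueError on a non-positive
    denominator; callers that know the stratum raise the structured error.
    """
    if denominator is None or denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / denominator * PER


def percent_share(count: int, total: int) -> float:
    """Share of ``count`` in ``total`` as a percentage."""
    if total <= 0:
        raise UndefinedShareError(f"cannot take a share of a zero total (count={count})")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / total * 100.0


def _report_level(report, axis: StratumAxis) -> str | None:
    """The report's level on an axis, or None when unknown on that axis."""
    if axis == StratumAxis.TOTAL:
        return ALL_LEVEL
    if axis == StratumAxis.SEX:
        return None if report.sex == Sex.UNKNOWN else report.sex.value
    if axis == StratumAxis.AGE:
        return report.age_band
    if axis == StratumAxis.MANUFACTURER:
        m = report.manufacturer
        return None if m in (Manufacturer.UNKNOWN, Manufacturer.OTHER) else m.value
    raise ValueError(f"unknown axis {axis}")


def count_reports(
    grouped: Iterable[GroupedReport],
    series: DoseSeries,
    axis: StratumAxis,
) -> dict[tuple[str, str], int]:
    """Report counts per (group, level) for one series and axis.

    The pseudo-group ``ANY`` counts reports carrying at least one group.
    Reports whose level on the axis is unknown are excluded from level rows
    but still appear under the TOTAL axis (level ``ALL``), which callers
    request separately.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for gr in grouped:
        if gr.report.dose_series != series or not gr.groups:
            continue
        level = _report_level(gr.report, axis)
        if level is None:
            continue
        counts[(ANY_GROUP, level)] += 1
        for g in gr.groups:
            counts[(g, level)] += 1
    return dict(counts)


@dataclass
class StratifiedCountTable:
    """Per (group x series x axis x level) counts, shares, rates and p-values.

    Backed by a DataFrame with columns
    ``group, series, axis, level, count, pct, ir_per_100k, p_value``.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "group", "series", "axis", "level",
                "count", "pct", "ir_per_100k", "p_value",
            ]
        )
    )

    def row(self, group: str, series: str, axis: str, level: str) -> pd.Series:
        f = self.frame
        sel = f[
            (f["group"] == group) & (f["series"] == series)
            & (f["axis"] == axis) & (f["level"] == level)
        ]
        if len(sel) != 1:
            raise KeyError(f"{len(sel)} rows for {(group, series, axis, level)}")
        return sel.iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


def build_table(
    grouped: Sequence[GroupedReport],
    denominators: DenominatorTable,
    series: DoseSeries,
    axes: Sequence[StratumAxis],
    groups: Sequence[str] | None = None,
) -> StratifiedCountTable:
    """Assemble the stratified incidence table for one report series.

    For the MANUFACTURER axis the denominator population is the
    at-least-one-dose (ALOD) series when the report series is CPS, because
    no per-manufacturer primary-series denominators are published; report
    counts stay series-scoped. Manufacturer levels without a published
    denominator (e.g. a vaccine never authorized for the booster series)
    are omitted rather than treated as errors.

    ``groups`` fixes the row universe (zero rows are emitted for groups
    unseen in the corpus); by default the groups observed in the corpus.
    """
    if groups is None:
        groups = sorted({g for gr in grouped for g in gr.groups})
    rows = []
    for axis in axes:
        counts = count_reports(grouped, series, axis)
        if axis == StratumAxis.MANUFACTURER:
            den_series = DoseSeries.ALOD if series == DoseSeries.CPS else series
            levels = [
                lvl for lvl in AXIS_LEVELS[axis]
                if (den_series, axis, lvl) in denominators.entries
            ]
            if not levels:
                raise MissingDenominatorError(den_series.value, axis.value, "*")
        else:
            den_series = series
            levels = list(AXIS_LEVELS[axis])
        for level in levels:
            denom = denominators.lookup(den_series, axis, level)
            any_count = counts.get((ANY_GROUP, level), 0)
            for group in [ANY_GROUP, *groups]:
                c = counts.get((group, level), 0)
                rows.append(
                    {
                        "group": group,
                        "series": series.value,
                        "axis": axis.value,
                        "level": level,
                        "count": c,
                        "pct": np.nan
                        if (group == ANY_GROUP or any_count == 0)
                        else percent_share(c, any_count),
                        "ir_per_100k": incidence_rate(c, denom),
                        "p_value": np.nan,
                    }
                )
    return StratifiedCountTable(pd.DataFrame(rows))
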