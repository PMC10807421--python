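"""Core domain types for spontaneous-report analysis.

The counting unit throughout is the *report* (one VAERS-style identifier),
not the person: passive surveillance data cannot link multiple reports from
the same individual, so rates and shares are per report.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .errors import MappingConfigError, MissingDenominatorError


class Sex(str, Enum):
    M = "M"
    F = "F"
    UNKNOWN = "UNKNOWN"


class Manufacturer(str, Enum):
    PFIZER_BIONTECH = "PFIZER_BIONTECH"
    MODERNA = "MODERNA"
    JANSSEN = "JANSSEN"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class DoseSeries(str, Enum):
    """Denominator population a report is assigned to.

    CPS — completed primary series; UBB — updated bivalent booster;
    ALOD — at least one dose (used only as a denominator population, when
    the source publishes no per-manufacturer CPS counts).
    """

    CPS = "CPS"
    UBB = "UBB"
    ALOD = "ALOD"
    UNKNOWN = "UNKNOWN"


class StratumAxis(str, Enum):
    TOTAL = "TOTAL"
    SEX = "SEX"
    AGE = "AGE"
    MANUFACTURER = "MANUFACTURER"


#: Half-open age bands in integer years: [0,18), [18,50), [50,65), [65,inf).
AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("0-17", 0.0, 18.0),
    ("18-49", 18.0, 50.0),
    ("50-64", 50.0, 65.0),
    ("65+", 65.0, math.inf),
)

#: Pseudo-group counting reports with at least one mapped group ("Any" row).
ANY_GROUP = "ANY"

#: Level label for the TOTAL axis.
ALL_LEVEL = "ALL"

MAX_AGE_YEARS = 130.0


def age_band(age_years: float | None) -> str | None:
    """Return the age-band label for an age in years, or None if unknown."""
    if age_years is None:
        return None
    for label, lo, hi in AGE_BANDS:
        if lo <= age_years < hi:
            return label
    return None


@dataclass(frozen=True)
class AEReport:
    """One spontaneous adverse-event report.

    ``preferred_terms`` is a deduplicated set of MedDRA preferred-term
    strings; ``age_years`` is None when unknown.
    """

    report_id: str
    vaccine_types: frozenset[str]
    manufacturer: Manufacturer
    dose_series: DoseSeries
    sex: Sex
    age_years: float | None
    preferred_terms: frozenset[str]

    def __post_init__(self):
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if any(not pt for pt in self.preferred_terms):
            raise ValueError(f"report {self.report_id}: empty preferred term")
        if self.age_years is not None:
            if not math.isfinite(self.age_years) or self.age_years < 0:
                raise ValueError(f"report {self.report_id}: invalid age {self.age_years}")
            if self.age_years >= MAX_AGE_YEARS:
                raise ValueError(f"report {self.report_id}: implausible age {self.age_years}")

    @property
    def age_band(self) -> str | None:
        return age_band(self.age_years)


@dataclass
class DenominatorTable:
    """Vaccinated-person counts keyed by (series, axis, level).

    Levels and totals are published independently by the source, so the sum
    of levels on an axis may fall short of the TOTAL entry; a mismatch is
    tolerated (callers may log it) but a level sum *exceeding* the total on
    the same axis is rejected by :meth:`check_consistency`.
    """

    entries: dict[tuple[DoseSeries, StratumAxis, str], int] = field(default_factory=dict)

    def add(self, series: DoseSeries, axis: StratumAxis, level: str, persons: int) -> None:
        key = (series, axis, level)
        if persons < 0:
            raise ValueError(f"negative denominator for {key}: {persons}")
        if key in self.entries:
            raise ValueError(f"duplicate denominator entry for {key}")
        self.entries[key] = int(persons)

    def lookup(self, series: DoseSeries, axis: StratumAxis, level: str) -> int:
        try:
            return self.entries[(series, axis, level)]
        except KeyError:
            raise MissingDenominatorError(series.value, axis.value, level) from None

    def levels(self, series: DoseSeries, axis: StratumAxis) -> list[str]:
        return [lvl for (s, a, lvl) in self.entries if s == series and a == axis]

    def check_consistency(self) -> list[str]:
        """Return human-readable notes for axes whose level sum differs from TOTAL."""
        notes = []
        series_seen = {s for (s, _, _) in self.entries}
        for s in series_seen:
            total = self.entries.get((s, StratumAxis.TOTAL, ALL_LEVEL))
            if total is None:
                continue
            for axis in (StratumAxis.SEX, StratumAxis.AGE):
                lvls = self.levels(s, axis)
                if not lvls:
                    continue
                ssum = sum(self.entries[(s, axis, l)] for l in lvls)
                if ssum > total:
                    raise ValueError(
                        f"{s.value}/{axis.value}: level sum {ssum} exceeds total {total}"
                    )
                if ssum != total:
                    notes.append(
                        f"{s.value}/{axis.value}: levels sum to {ssum:,} "
                        f"vs total {total:,} (published independently)"
                    )
        return notes

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PTGroupMap:
    """Preferred-term → adverse-event-group dictionary.

    ``unmapped_policy`` controls what happens to a PT absent from the map:
    ``"DROP"`` ignores it silently, ``"ERROR"`` raises
    :class:`~otosignal.errors.UnmappedTermError`.
    """

    mapping: dict[str, str]
    groups: tuple[str, ...]
    unmapped_policy: str = "DROP"

    def __post_init__(self):
        if self.unmapped_policy not in ("DROP", "ERROR"):
            raise MappingConfigError(f"unknown unmapped policy {self.unmapped_policy!r}")
        known = set(self.groups)
        for pt, grp in self.mapping.items():
            if grp not in known:
                raise MappingConfigError(
                    f"PT {pt!r} maps to undeclared group {grp!r}"
                )

    @classmethod
    def from_group_lists(
        cls,
        group_to_pts: Mapping[str, Iterable[str]],
        unmapped_policy: str = "DROP",
    ) -> "PTGroupMap":
        """Invert a {group: [PT, ...]} config; a PT under two groups is an error."""
        mapping: dict[str, str] = {}
        for grp, pts in group_to_pts.items():
            for pt in pts:
                pt = str(pt).strip()
                if not pt:
                    raise MappingConfigError(f"group {grp!r} lists an empty PT")
                if pt in mapping and mapping[pt] != grp:
                    raise MappingConfigError(
                        f"PT {pt!r} is listed under both {mapping[pt]!r} and {grp!r}"
                    )
                mapping[pt] = grp
        return cls(mapping=mapping, groups=tuple(group_to_pts), unmapped_policy=unmapped_policy)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class GroupedReport:
    """A report together with the set of adverse-event groups it maps to."""

    report: AEReport
    groups: frozenset[str]


@dataclass
class GroupCounts:
    """Per-group report counts plus the total report count of a corpus.

    ``counts[g]`` is the number of *reports* mentioning group ``g`` (a report
    counts at most once per group); ``total_reports`` is the corpus size and
    serves as the n (index) or N - n (background) term of the PRR.
    """

    counts: dict[str, int]
    total_reports: int

    def __post_init__(self):
        if self.total_reports < 0:
            raise ValueError("total_reports must be >= 0")
        for g, c in self.counts.items():
            if c < 0 or c > self.total_reports:
                raise ValueError(f"group {g!r}: count {c} outside [0, {self.total_reports}]")
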