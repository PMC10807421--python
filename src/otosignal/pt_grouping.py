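"""Map MedDRA preferred terms onto adverse-event groups.

A report counts at most once per group regardless of how many of its PTs
fall in that group (three tinnitus-family terms contribute a single
tinnitus hit), and a report contributes to every group it maps to —
exclusivity is not forced.
"""
from __future__ import annotations

from typing import Iterable, Sequence

from .errors import UnmappedTermError
from .models import AEReport, GroupedReport, PTGroupMap


def assign_groups(report: AEReport, group_map: PTGroupMap) -> GroupedReport:
    """Resolve a report's preferred terms to its (deduplicated) group set.

    Under policy ``DROP`` unmapped PTs are ignored; under ``ERROR`` the
    first unmapped PT (alphabetically, for determinism) raises
    :class:`~otosignal.errors.UnmappedTermError`.
    """
    groups = set()
    for pt in sorted(report.preferred_terms):
        grp = group_map.mapping.get(pt)
        if grp is None:
            if group_map.unmapped_policy == "ERROR":
                raise UnmappedTermError(pt)
            continue
        groups.add(grp)
    return GroupedReport(report=report, groups=frozenset(groups))


def select_otolaryngologic(
    reports: Iterable[AEReport], group_map: PTGroupMap
) -> list[GroupedReport]:
    """Grouped reports carrying at least one mapped group, sorted by report id."""
    selected = []
    for report in reports:
        gr = assign_groups(report, group_map)
        if gr.groups:
            selected.append(gr)
    selected.sort(key=lambda gr: gr.report.report_id)
    return selected


def group_counts(grouped: Sequence[GroupedReport]) -> dict[str, int]:
    """Number of reports per group (each report once per group)."""
    counts: dict[str, int] = {}
    for gr in grouped:
        for g in gr.groups:
            counts[g] = counts.get(g, 0) + 1
    return counts
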