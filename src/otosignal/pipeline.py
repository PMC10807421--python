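"""End-to-end orchestration: load -> group -> incidence -> tests -> PRR.

The pipeline is linear and deterministic: the same inputs always produce
byte-identical output tables. It writes one incidence table per stratum
axis (sex, age, manufacturer), the PRR table, and a JSON manifest that
records the inputs (with checksums), the configuration and the package
version, which together suffice to reproduce the run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import DegenerateTableError, stratum_event_table, apply_test
from .disproportionality import prr_table
from .errors import ConfigurationError
from .incidence import AXIS_LEVELS, StratifiedCountTable, build_table
from .models import ANY_GROUP, DenominatorTable, DoseSeries, GroupCounts, StratumAxis
from .pt_grouping import group_counts, select_otolaryngologic
from .vaers_io import (
    DEFAULT_VACCINE_FILTER,
    default_group_map,
    read_denominators,
    read_group_map,
    read_reports,
    write_result_table,
)

log = logging.getLogger(__name__)

_STAGES = ("load", "group", "incidence", "tests", "prr")

_AXIS_FILES = {
    StratumAxis.SEX: "table1_sex.tsv",
    StratumAxis.AGE: "table2_age.tsv",
    StratumAxis.MANUFACTURER: "table3_manufacturer.tsv",
}


@dataclass
class RunConfig:
    """Inputs, statistical settings and output location for one run."""

    data_path: Path
    vax_path: Path
    symptoms_path: Path
    denominators_path: Path
    out_dir: Path
    mapping_path: Path | None = None
    series: str = "cps"  # cps | ubb | both
    axes: tuple[StratumAxis, ...] = (
        StratumAxis.SEX,
        StratumAxis.AGE,
        StratumAxis.MANUFACTURER,
    )
    signal_threshold: float = 2.0
    alpha: float = 0.05
    continuity: bool = False
    stop_after: str | None = None

    def __post_init__(self):
        if self.signal_threshold <= 0:
            raise ConfigurationError(f"signal threshold must be > 0, got {self.signal_threshold}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.series not in ("cps", "ubb", "both"):
            raise ConfigurationError(f"series must be cps, ubb or both, got {self.series!r}")
        if self.stop_after is not None and self.stop_after not in _STAGES:
            raise ConfigurationError(f"stop_after must be one of {_STAGES}")

    @property
    def selected_series(self) -> tuple[DoseSeries, ...]:
        if self.series == "both":
            return (DoseSeries.CPS, DoseSeries.UBB)
        return (DoseSeries(self.series.upper()),)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def attach_association_tests(
    table: StratifiedCountTable,
    denominators: DenominatorTable,
    series: DoseSeries,
    axis: StratumAxis,
) -> None:
    """Fill the p-value column of one (series, axis) slice, in place.

    For every group (including the ANY row) an r x 2 event/non-event table
    across the axis levels is tested; the group's p-value is repeated on
    each of its level rows. Degenerate tables (no events) keep p = NaN.
    """
    frame = table.frame
    sel = (frame["series"] == series.value) & (frame["axis"] == axis.value)
    if not sel.any():
        return
    den_series = (
        DoseSeries.ALOD
        if axis == StratumAxis.MANUFACTURER and series == DoseSeries.CPS
        else series
    )
    levels = [
        lvl
        for lvl in AXIS_LEVELS[axis]
        if (den_series, axis, lvl) in denominators.entries
        and ((frame["level"] == lvl) & sel).any()
    ]
    if len(levels) < 2:
        return
    sizes = [denominators.lookup(den_series, axis, lvl) for lvl in levels]
    for group in frame.loc[sel, "group"].unique():
        counts = [
            int(
                frame.loc[
                    sel & (frame["group"] == group) & (frame["level"] == lvl), "count"
                ].iloc[0]
            )
            for lvl in levels
        ]
        try:
            result = apply_test(stratum_event_table(counts, sizes))
        except DegenerateTableError:
            continue
        frame.loc[sel & (frame["group"] == group), "p_value"] = result.p_value


@dataclass
class RunResult:
    tables: dict[str, Path] = field(default_factory=dict)
    manifest_path: Path | None = None


def run(config: RunConfig) -> RunResult:
    """Execute the pipeline and write the result tables and manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    group_map = (
        default_group_map()
        if config.mapping_path is None
        else read_group_map(config.mapping_path)
    )
    denominators = read_denominators(config.denominators_path)
    reports = read_reports(
        config.data_path, config.vax_path, config.symptoms_path, vaccine_type_filter=None
    )
    index_reports = [r for r in reports if r.vaccine_types & DEFAULT_VACCINE_FILTER]
    background_reports = [r for r in reports if not (r.vaccine_types & DEFAULT_VACCINE_FILTER)]
    log.info(
        "loaded %d reports (%d index, %d background)",
        len(reports), len(index_reports), len(background_reports),
    )
    result = RunResult()
    if config.stop_after == "load":
        return result

    grouped_index = select_otolaryngologic(index_reports, group_map)
    grouped_background = select_otolaryngologic(background_reports, group_map)
    if config.stop_after == "group":
        return result

    groups = [g for g in group_map.groups]
    tables: dict[StratumAxis, StratifiedCountTable] = {}
    for axis in config.axes:
        frames = []
        for series in config.selected_series:
            t = build_table(
                grouped_index, denominators, series,
                axes=[StratumAxis.TOTAL, axis], groups=groups,
            )
            if config.stop_after not in ("incidence",):
                attach_association_tests(t, denominators, series, axis)
            frames.append(t.frame)
        tables[axis] = StratifiedCountTable(pd.concat(frames, ignore_index=True))

    for axis, table in tables.items():
        path = out / _AXIS_FILES[axis]
        write_result_table(table, path)
        result.tables[_AXIS_FILES[axis]] = path
    if config.stop_after in ("incidence", "tests"):
        _write_manifest(config, result, out)
        return result

    selected = set(config.selected_series)
    index_for_prr = [gr for gr in grouped_index if gr.report.dose_series in selected]
    n_index = sum(1 for r in index_reports if r.dose_series in selected)
    index_counts = GroupCounts(group_counts(index_for_prr), n_index)
    background_counts = GroupCounts(
        group_counts(grouped_background), len(background_reports)
    )
    prr_results = prr_table(
        index_counts, background_counts,
        threshold=config.signal_threshold, alpha=config.alpha,
        continuity=config.continuity,
    )
    prr_path = out / "table4_prr.tsv"
    write_result_table(prr_results, prr_path)
    result.tables["table4_prr.tsv"] = prr_path

    _write_manifest(config, result, out)
    return result


def _write_manifest(config: RunConfig, result: RunResult, out: Path) -> None:
    cfg = dataclasses.asdict(config)
    cfg = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in cfg.items()
    }
    cfg["axes"] = [a.value for a in config.axes]
    manifest = {
        "version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("data", config.data_path),
                ("vax", config.vax_path),
                ("symptoms", config.symptoms_path),
                ("denominators", config.denominators_path),
                *(
                    (("mapping", config.mapping_path),)
                    if config.mapping_path is not None
                    else ()
                ),
            )
        },
        "config": cfg,
        "outputs": sorted(result.tables),
    }
    path = out / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.manifest_path = path
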