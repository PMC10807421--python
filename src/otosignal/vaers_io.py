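"""Readers and writers for the VAERS-dialect file layout.

The public spontaneous-report export comes as three delimited files sharing
a report key:

* DATA   — ``VAERS_ID, AGE_YRS, SEX`` (demographics, one row per report);
* VAX    — ``VAERS_ID, VAX_TYPE, VAX_MANU, VAX_DOSE_SERIES`` (one row per
  vaccine record, several per report allowed);
* SYMPTOMS — ``VAERS_ID, SYMPTOM1..SYMPTOM5`` (MedDRA preferred terms,
  several rows per report allowed).

Real exports are Latin-1 encoded; files are read as UTF-8 with a Latin-1
fallback. Reports are assigned to a denominator series by vaccine type:
a bivalent-booster record (``COVID19-2``) puts the report in the UBB
series, otherwise a primary-series record (``COVID19``) puts it in CPS.
"""
from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .disproportionality import PRRResult
from .errors import MissingColumnError, VaersLoadError
from .incidence import StratifiedCountTable
from .models import (
    AEReport,
    DenominatorTable,
    DoseSeries,
    Manufacturer,
    MAX_AGE_YEARS,
    PTGroupMap,
    Sex,
    StratumAxis,
)

log = logging.getLogger(__name__)

COVID_PRIMARY_TYPE = "COVID19"
COVID_BIVALENT_TYPE = "COVID19-2"
DEFAULT_VACCINE_FILTER = frozenset({COVID_PRIMARY_TYPE, COVID_BIVALENT_TYPE})

_SYMPTOM_COL = re.compile(r"^SYMPTOM\d+$")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except UnicodeDecodeError:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="latin-1")
    except FileNotFoundError:
        raise VaersLoadError(f"input file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise VaersLoadError(f"could not parse {path}: {exc}") from None


def _require(frame: pd.DataFrame, path, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in frame.columns:
            raise MissingColumnError(path, col)


def parse_manufacturer(token: str) -> Manufacturer:
    t = re.sub(r"[\\/.\s-]+", "_", token.strip().upper())
    if "PFIZER" in t or "BIONTECH" in t:
        return Manufacturer.PFIZER_BIONTECH
    if "MODERNA" in t:
        return Manufacturer.MODERNA
    if "JANSSEN" in t:
        return Manufacturer.JANSSEN
    if not t or "UNKNOWN" in t:
        return Manufacturer.UNKNOWN
    return Manufacturer.OTHER


def _parse_sex(token: str) -> Sex:
    t = token.strip().upper()
    return Sex(t) if t in ("M", "F") else Sex.UNKNOWN


def _parse_age(token: str, report_id: str) -> float | None:
    t = token.strip()
    if not t:
        return None
    try:
        age = float(t)
    except ValueError:
        log.warning("report %s: unparseable age %r treated as unknown", report_id, t)
        return None
    if not np.isfinite(age) or age < 0 or age >= MAX_AGE_YEARS:
        log.warning("report %s: implausible age %s treated as unknown", report_id, age)
        return None
    return age


def _series_for(types: frozenset[str]) -> DoseSeries:
    # A booster record supersedes: a report carrying both vaccine types is UBB.
    if COVID_BIVALENT_TYPE in types:
        return DoseSeries.UBB
    if COVID_PRIMARY_TYPE in types:
        return DoseSeries.CPS
    return DoseSeries.UNKNOWN


def read_reports(
    data_path,
    vax_path,
    symptoms_path,
    vaccine_type_filter: Iterable[str] | None = DEFAULT_VACCINE_FILTER,
) -> list[AEReport]:
    """Load and join the three report files into one AEReport per report key.

    Reports with no vaccine type inside ``vaccine_type_filter`` are
    excluded (pass None to keep everything). Symptom rows for the same key
    are merged by set union; duplicate demographic rows keep the first
    occurrence with a warning.
    """
    data = _read_csv(data_path)
    _require(data, data_path, ("VAERS_ID", "AGE_YRS", "SEX"))
    vax = _read_csv(vax_path)
    _require(vax, vax_path, ("VAERS_ID", "VAX_TYPE", "VAX_MANU", "VAX_DOSE_SERIES"))
    symptoms = _read_csv(symptoms_path)
    _require(symptoms, symptoms_path, ("VAERS_ID",))
    symptom_cols = [c for c in symptoms.columns if _SYMPTOM_COL.match(c)]
    if not symptom_cols:
        raise MissingColumnError(symptoms_path, "SYMPTOM1")

    if data["VAERS_ID"].duplicated().any():
        dupes = data.loc[data["VAERS_ID"].duplicated(), "VAERS_ID"].unique()
        log.warning(
            "%d duplicate demographic rows (first record wins): %s",
            len(dupes), ", ".join(dupes[:5]),
        )
        data = data.drop_duplicates("VAERS_ID", keep="first")

    demo = data.set_index("VAERS_ID")

    vax_types: dict[str, set[str]] = {}
    vax_manu: dict[str, Manufacturer] = {}
    for rid, vtype, manu in zip(vax["VAERS_ID"], vax["VAX_TYPE"], vax["VAX_MANU"]):
        vtype = vtype.strip().upper()
        types = vax_types.setdefault(rid, set())
        types.add(vtype)
        # manufacturer from the first COVID record, else first record
        if rid not in vax_manu or (
            vtype in DEFAULT_VACCINE_FILTER
            and vax_manu[rid] in (Manufacturer.UNKNOWN, Manufacturer.OTHER)
        ):
            vax_manu[rid] = parse_manufacturer(manu)

    pts: dict[str, set[str]] = {}
    for _, row in symptoms.iterrows():
        bag = pts.setdefault(row["VAERS_ID"], set())
        for col in symptom_cols:
            term = str(row[col]).strip()
            if term:
                bag.add(term)

    wanted = None if vaccine_type_filter is None else frozenset(vaccine_type_filter)
    reports: list[AEReport] = []
    for rid in list(dict.fromkeys(list(data["VAERS_ID"]) + list(vax["VAERS_ID"]))):
        types = frozenset(vax_types.get(rid, set()))
        if wanted is not None and not (types & wanted):
            continue
        if rid in demo.index:
            row = demo.loc[rid]
            sex = _parse_sex(row["SEX"])
            age = _parse_age(row["AGE_YRS"], rid)
        else:
            sex, age = Sex.UNKNOWN, None
        reports.append(
            AEReport(
                report_id=rid,
                vaccine_types=types,
                manufacturer=vax_manu.get(rid, Manufacturer.UNKNOWN),
                dose_series=_series_for(types),
                sex=sex,
                age_years=age,
                preferred_terms=frozenset(pts.get(rid, set())),
            )
        )
    return reports


def read_denominators(path) -> DenominatorTable:
    """Load a (series, axis, level, persons) CSV into a DenominatorTable.

    Thousands separators in the persons column are tolerated. Negative
    counts and duplicate strata are load errors.
    """
    frame = _read_csv(path)
    _require(frame, path, ("series", "axis", "level", "persons"))
    table = DenominatorTable()
    for _, row in frame.iterrows():
        try:
            series = DoseSeries(row["series"].strip().upper())
            axis = StratumAxis(row["axis"].strip().upper())
        except ValueError as exc:
            raise VaersLoadError(f"{path}: {exc}") from None
        raw = row["persons"].replace(",", "").strip()
        try:
            persons = int(raw)
        except ValueError:
            raise VaersLoadError(
                f"{path}: unparseable persons count {row['persons']!r} "
                f"for {series.value}/{axis.value}/{row['level']}"
            ) from None
        try:
            table.add(series, axis, row["level"].strip(), persons)
        except ValueError as exc:
            raise VaersLoadError(f"{path}: {exc}") from None
    for note in table.check_consistency():
        log.warning("denominator table %s: %s", path, note)
    return table


def read_group_map(path) -> PTGroupMap:
    """Load a YAML {group: [PT, ...]} mapping config.

    Accepts either a top-level mapping of group names to PT lists or a
    document with ``groups:`` and optional ``unmapped_policy:`` keys.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise VaersLoadError(f"{path}: mapping config must be a non-empty mapping")
    policy = "DROP"
    if "groups" in doc:
        policy = str(doc.get("unmapped_policy", "DROP")).upper()
        doc = doc["groups"]
    return PTGroupMap.from_group_lists(doc, unmapped_policy=policy)


def default_group_map() -> PTGroupMap:
    """The shipped 19-group seed mapping."""
    ref = resources.files("otosignal") / "data" / "default_groups.yaml"
    with resources.as_file(ref) as path:
        return read_group_map(path)


def _fmt_pct(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.2f}"


def _fmt_ir(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.3f}"


def format_p(p: float) -> str:
    """Display convention: p below 0.001 prints as ``<0.001``."""
    if pd.isna(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def write_result_table(table, path) -> None:
    """Write a stratified incidence table or PRR results as TSV.

    IRs print at 3 decimals, shares at 2 (half-even), p-values below 0.001
    as ``<0.001``; an empty table yields a header-only file.
    """
    path = Path(path)
    if isinstance(table, StratifiedCountTable):
        out = table.frame.copy()
        out["pct"] = out["pct"].map(_fmt_pct)
        out["ir_per_100k"] = out["ir_per_100k"].map(_fmt_ir)
        out["p_value"] = out["p_value"].map(format_p)
        out.to_csv(path, sep="\t", index=False)
        return
    rows = list(table)
    if rows and not all(isinstance(r, PRRResult) for r in rows):
        raise TypeError("write_result_table expects a StratifiedCountTable or PRRResults")
    frame = pd.DataFrame(
        [
            {
                "group": r.group,
                "m": r.m,
                "n": r.n,
                "M": r.M,
                "N": r.N,
                "prr": _fmt_ir(r.prr),
                "ci_low": _fmt_ir(r.ci_low),
                "ci_high": _fmt_ir(r.ci_high),
                "signal": str(bool(r.signal)).lower(),
            }
            for r in rows
        ],
        columns=["group", "m", "n", "M", "N", "prr", "ci_low", "ci_high", "signal"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_result_table(path) -> StratifiedCountTable:
    """Re-read a written incidence table (round-trips counts and keys exactly)."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"group": str, "series": str, "axis": str, "level": str},
        keep_default_na=False,
    )
    for col in ("group", "series", "axis", "level"):
        if col not in frame.columns:
            raise MissingColumnError(path, col)
    frame["count"] = frame["count"].astype(np.int64)
    for col in ("pct", "ir_per_100k"):
        frame[col] = pd.to_numeric(frame[col].replace("", np.nan))
    frame["p_value"] = pd.to_numeric(
        frame["p_value"].astype(str).str.lstrip("<").replace("", np.nan),
        errors="coerce",
    )
    return StratifiedCountTable(frame)
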