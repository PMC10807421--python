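"""Generate spontaneous-report corpora shaped like the public VAERS export.

The generator emits the three-file report layout (demographics, vaccine
records, symptom rows), a denominator table, a matching PT->group mapping
config, and a ground-truth record, so that every pipeline stage can be
exercised and checked against known parameters without any download.

Default parameters emulate the published otolaryngologic AEFI corpus:
per-group baseline probabilities are the published CPS group shares, the
background group probabilities are those shares deflated by the published
PRRs, the sex/age/manufacturer mix follows the published report
distribution, and the denominators are the published vaccinated-population
sample sizes. Groups are sampled independently per report unless an
explicit pairwise co-occurrence boost is configured.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .models import AGE_BANDS, DenominatorTable, DoseSeries, StratumAxis
from . import refdata
from .refdata import replay_fixture_tables  # re-exported: desk-scale replay fixture

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimOutput",
    "generate",
    "default_index_group_probs",
    "default_background_group_probs",
    "default_stratum_mix",
    "replay_fixture_tables",
]

#: Filler preferred terms for reports with no otolaryngologic group; they
#: stay unmapped and exercise the DROP policy.
_FILLER_PTS = ("Headache", "Pyrexia", "Fatigue", "Injection site pain")

_MANU_TOKEN = {
    "PFIZER_BIONTECH": "PFIZER\\BIONTECH",
    "MODERNA": "MODERNA",
    "JANSSEN": "JANSSEN",
}


def default_index_group_probs() -> dict[str, float]:
    """Per-group probability that an index report mentions the group.

    Taken from the published CPS corpus: group count / total otolaryngologic
    reports (106,653).
    """
    any_total = refdata.reference_any_counts()[
        (DoseSeries.CPS, StratumAxis.TOTAL, "ALL")
    ]
    return {
        c.group: c.count / any_total
        for c in refdata.reference_cells()
        if c.series == DoseSeries.CPS
        and c.axis == StratumAxis.TOTAL
        and c.group != "ANY"
    }


def default_background_group_probs() -> dict[str, float]:
    """Background probabilities implied by the published PRRs (index / PRR)."""
    idx = default_index_group_probs()
    return {g: idx[g] / refdata.REFERENCE_PRR[g][1] for g in idx}


def default_stratum_mix() -> dict[str, dict[str, float]]:
    """Sex / age-band / manufacturer mix of the published report corpus."""
    any_counts = refdata.reference_any_counts()
    sex_m = any_counts[(DoseSeries.CPS, StratumAxis.SEX, "M")]
    sex_f = any_counts[(DoseSeries.CPS, StratumAxis.SEX, "F")]
    ages = {
        band: any_counts[(DoseSeries.CPS, StratumAxis.AGE, band)]
        for band, _, _ in AGE_BANDS
    }
    age_total = sum(ages.values())
    manu = refdata.MANUFACTURER_REPORT_TOTALS
    manu_total = sum(manu.values())
    return {
        "sex": {"M": sex_m / (sex_m + sex_f), "F": sex_f / (sex_m + sex_f)},
        "age": {band: v / age_total for band, v in ages.items()},
        "manufacturer": {k: v / manu_total for k, v in manu.items()},
    }


@dataclass
class SimConfig:
    """Parameters of one simulated reporting corpus.

    ``planted_effects`` multiplies the index-corpus probability of the named
    groups (capped at 1, with a warning recorded in the ground truth);
    ``missing_sex`` / ``missing_age`` are probabilities of an unknown value;
    ``pt_per_group`` synonym PTs are generated per group to exercise
    per-report deduplication; ``cooccurrence`` optionally boosts group B's
    probability by a factor within reports that drew group A.
    """

    seed: int = 0
    n_index_reports: int = 20_000
    n_background_reports: int = 40_000
    group_probs: dict[str, float] = field(default_factory=default_index_group_probs)
    background_group_probs: dict[str, float] = field(
        default_factory=default_background_group_probs
    )
    stratum_mix: dict[str, dict[str, float]] = field(default_factory=default_stratum_mix)
    denominators: DenominatorTable = field(default_factory=refdata.reference_denominators)
    planted_effects: dict[str, float] = field(default_factory=dict)
    missing_sex: float = 0.0
    missing_age: float = 0.0
    pt_per_group: int = 3
    series: str = "CPS"
    cooccurrence: tuple[str, str, float] | None = None

    def __post_init__(self):
        for name, p in (("missing_sex", self.missing_sex), ("missing_age", self.missing_age)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for g, p in {**self.group_probs, **self.background_group_probs}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"group {g!r}: probability {p} outside [0, 1]")
        for g, mult in self.planted_effects.items():
            if mult <= 0:
                raise ConfigurationError(f"planted multiplier for {g!r} must be > 0")
            if g not in self.group_probs:
                raise ConfigurationError(f"planted effect names unknown group {g!r}")
        for axis, mix in self.stratum_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"stratum mix for {axis!r} sums to {total}, not 1")
        if self.pt_per_group < 1:
            raise ConfigurationError("pt_per_group must be >= 1")
        if self.series not in ("CPS", "UBB"):
            raise ConfigurationError(f"series must be CPS or UBB, got {self.series!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "planted_effects" in doc:
            doc["planted_effects"] = dict(doc["planted_effects"])
        return cls(**doc)


@dataclass
class GroundTruth:
    """Exact generator parameters behind a simulated corpus.

    ``implied_prr[g]`` is the asymptotic PRR
    p_index(g) / p_background(g) under the generator's independence
    assumptions (effective, post-capping index probability).
    """

    p_index: dict[str, float]
    p_background: dict[str, float]
    implied_prr: dict[str, float]
    expected_index_count: dict[str, int | float]
    true_ir_per_100k: dict[str, dict[str, float]]
    warnings: list[str]

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, float) and not np.isfinite(obj):
                return None  # infinite implied PRR (background probability 0)
            return obj

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_clean(self.__dict__), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SimOutput:
    data_path: Path
    vax_path: Path
    symptoms_path: Path
    denominators_path: Path
    mapping_path: Path
    ground_truth_path: Path
    ground_truth: GroundTruth


def _synonym_pts(group: str, k: int) -> list[str]:
    """Synthetic preferred-term synonyms for one group (synthetic vocabulary)."""
    return [f"{group} [syn {j}]" for j in range(1, k + 1)]


def _sample_ages(rng: np.random.Generator, bands: Sequence[str]) -> np.ndarray:
    lows = {label: lo for label, lo, _ in AGE_BANDS}
    highs = {label: (89 if np.isinf(hi) else int(hi) - 1) for label, _, hi in AGE_BANDS}
    return np.array(
        [rng.integers(lows[b], highs[b] + 1) for b in bands], dtype=float
    )


def _draw_corpus(
    rng: np.random.Generator,
    n: int,
    probs: Mapping[str, float],
    config: SimConfig,
    id_start: int,
    vax_type: str,
    manufacturers: Sequence[str] | None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    groups = list(probs)
    ids = [str(id_start + i) for i in range(n)]

    mix = config.stratum_mix
    sex_levels = list(mix["sex"])
    sex = rng.choice(sex_levels, size=n, p=[mix["sex"][s] for s in sex_levels])
    if config.missing_sex:
        sex = np.where(rng.random(n) < config.missing_sex, "", sex)
    band_levels = list(mix["age"])
    bands = rng.choice(band_levels, size=n, p=[mix["age"][b] for b in band_levels])
    ages = _sample_ages(rng, bands)
    age_str = np.array([f"{a:.0f}" for a in ages])
    if config.missing_age:
        age_str = np.where(rng.random(n) < config.missing_age, "", age_str)

    if manufacturers is None:
        manu = np.repeat("OTHER MANUFACTURER", n)
    else:
        mmix = mix["manufacturer"]
        manu_raw = rng.choice(list(mmix), size=n, p=list(mmix.values()))
        manu = np.array([_MANU_TOKEN[m] for m in manu_raw])

    hits = rng.random((n, len(groups))) < np.array([probs[g] for g in groups])
    if config.cooccurrence is not None:
        ga, gb, boost = config.cooccurrence
        if ga in groups and gb in groups:
            ia, ib = groups.index(ga), groups.index(gb)
            extra_p = np.clip(probs[gb] * (boost - 1.0), 0.0, 1.0)
            extra = (rng.random(n) < extra_p) & hits[:, ia]
            hits[:, ib] |= extra

    synonyms = {g: _synonym_pts(g, config.pt_per_group) for g in groups}
    symptom_rows = []
    for i in range(n):
        pts: list[str] = []
        for j, g in enumerate(groups):
            if hits[i, j]:
                k = int(rng.integers(1, config.pt_per_group + 1))
                chosen = rng.choice(config.pt_per_group, size=k, replace=False)
                pts.extend(synonyms[g][c] for c in chosen)
        if not pts:
            pts = [_FILLER_PTS[int(rng.integers(0, len(_FILLER_PTS)))]]
        for start in range(0, len(pts), 5):
            chunk = pts[start : start + 5]
            symptom_rows.append(
                {"VAERS_ID": ids[i], **{f"SYMPTOM{j + 1}": (chunk[j] if j < len(chunk) else "")
                                        for j in range(5)}}
            )

    symptom_cols = ["VAERS_ID"] + [f"SYMPTOM{j}" for j in range(1, 6)]
    symptom_frame = pd.DataFrame(symptom_rows, columns=symptom_cols)
    data = pd.DataFrame({"VAERS_ID": ids, "AGE_YRS": age_str, "SEX": sex})
    vax = pd.DataFrame(
        {
            "VAERS_ID": ids,
            "VAX_TYPE": vax_type,
            "VAX_MANU": manu,
            "VAX_DOSE_SERIES": "2" if vax_type == "COVID19" else "3",
        }
    )
    return data, vax, symptom_frame


def generate(config: SimConfig, out_dir) -> SimOutput:
    """Write a simulated index + background corpus and its ground truth.

    Deterministic given ``config.seed``: a fixed seed reproduces the output
    files byte for byte. Index reports carry the COVID vaccine type of the
    configured series; background reports carry a non-COVID type so that
    the standard loader filter separates the corpora.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    warnings: list[str] = []
    p_index: dict[str, float] = {}
    for g, p in config.group_probs.items():
        eff = p * config.planted_effects.get(g, 1.0)
        if eff > 1.0:
            warnings.append(f"group {g!r}: planted probability {eff:.4f} capped at 1")
            eff = 1.0
        p_index[g] = eff
    p_background = {g: config.background_group_probs.get(g, 0.0) for g in config.group_probs}

    vax_type = "COVID19" if config.series == "CPS" else "COVID19-2"
    idx_frames = _draw_corpus(
        rng, config.n_index_reports, p_index, config,
        id_start=1_000_000, vax_type=vax_type,
        manufacturers=list(config.stratum_mix["manufacturer"]),
    )
    bg_frames = _draw_corpus(
        rng, config.n_background_reports, p_background, config,
        id_start=5_000_000, vax_type="OTHER", manufacturers=None,
    )

    data = pd.concat([idx_frames[0], bg_frames[0]], ignore_index=True)
    vax = pd.concat([idx_frames[1], bg_frames[1]], ignore_index=True)
    symptoms = pd.concat([idx_frames[2], bg_frames[2]], ignore_index=True)

    data_path = out / "DATA.csv"
    vax_path = out / "VAX.csv"
    symptoms_path = out / "SYMPTOMS.csv"
    data.to_csv(data_path, index=False)
    vax.to_csv(vax_path, index=False)
    symptoms.to_csv(symptoms_path, index=False)

    den_path = out / "denominators.csv"
    rows = [
        {"series": s.value, "axis": a.value, "level": lvl, "persons": persons}
        for (s, a, lvl), persons in sorted(
            config.denominators.entries.items(),
            key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2]),
        )
    ]
    pd.DataFrame(rows, columns=["series", "axis", "level", "persons"]).to_csv(
        den_path, index=False
    )

    mapping_path = out / "groups.yaml"
    with open(mapping_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "unmapped_policy": "DROP",
                "groups": {g: _synonym_pts(g, config.pt_per_group) for g in config.group_probs},
            },
            fh, allow_unicode=True, sort_keys=True,
        )

    series = DoseSeries(config.series)
    p_any = 1.0 - float(np.prod([1.0 - p for p in p_index.values()]))
    true_ir: dict[str, dict[str, float]] = {"TOTAL/ALL": {}}
    total_den = config.denominators.entries.get((series, StratumAxis.TOTAL, "ALL"))
    if total_den:
        true_ir["TOTAL/ALL"] = {
            g: config.n_index_reports * p / total_den * 1e5 for g, p in p_index.items()
        }
        true_ir["TOTAL/ALL"]["ANY"] = config.n_index_reports * p_any / total_den * 1e5
    for axis_name, axis in (("SEX", StratumAxis.SEX), ("AGE", StratumAxis.AGE)):
        mix = config.stratum_mix["sex" if axis == StratumAxis.SEX else "age"]
        for level, share in mix.items():
            den = config.denominators.entries.get((series, axis, level))
            if den:
                true_ir[f"{axis_name}/{level}"] = {
                    "ANY": config.n_index_reports * share * p_any / den * 1e5
                }

    truth = GroundTruth(
        p_index=p_index,
        p_background=p_background,
        implied_prr={
            g: (p_index[g] / p_background[g]) if p_background[g] > 0 else float("inf")
            for g in p_index
        },
        expected_index_count={g: config.n_index_reports * p for g, p in p_index.items()},
        true_ir_per_100k=true_ir,
        warnings=warnings,
    )
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)

    return SimOutput(
        data_path=data_path,
        vax_path=vax_path,
        symptoms_path=symptoms_path,
        denominators_path=den_path,
        mapping_path=mapping_path,
        ground_truth_path=truth_path,
        ground_truth=truth,
    )
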