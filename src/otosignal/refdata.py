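"""Published US COVID-19 otolaryngologic AEFI surveillance figures, typed in.

These are the printed per-stratum report counts, percentage shares and
incidence rates (per 100,000 vaccinated persons) from the public VAERS /
CDC COVID Data Tracker surveillance analysis of otorhinolaryngologic
adverse events following immunization, December 2020 – August 2023, for the
completed-primary-series (CPS), updated-bivalent-booster (UBB) and
at-least-one-dose (ALOD) populations.

They serve as a desk-scale replay fixture: the incidence stage of the
pipeline must reproduce every printed IR and percentage cell exactly (to
printed rounding) from the printed counts and population sample sizes.
Cells flagged as misprints are internally inconsistent in the published
table (e.g. a count that contradicts its own printed rate) and are excluded
from replay checks.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import ALL_LEVEL, ANY_GROUP, DenominatorTable, DoseSeries, StratumAxis

#: The 19 adverse-event group labels, as published.
REFERENCE_GROUPS: tuple[str, ...] = (
    "Hearing loss",
    "Tinnitus (Ringing in the ears)",
    "Ear infections (Otitis Media)",
    "Meniere’s disease",
    "Vestibular neuronitis",
    "Dizziness or vertigo",
    "Sinusitis",
    "Rhinitis (Allergic and Non-allergic)",
    "Epistaxis",
    "Anosmia",
    "Nasal polyps",
    "Snoring or difficulty breathing through the nose and sleep apnea",
    "Allergies",
    "Tonsillitis",
    "Laryngitis",
    "Vocal cord polyps and nodules",
    "Laryngopharyngeal reflux (acid reflux)",
    "Epiglottitis",
    "Pharyngitis",
)

# Column layouts: (series, axis, level) per cell column of each table block.
_SEX_COLS = (
    (DoseSeries.CPS, StratumAxis.TOTAL, ALL_LEVEL),
    (DoseSeries.CPS, StratumAxis.SEX, "M"),
    (DoseSeries.CPS, StratumAxis.SEX, "F"),
    (DoseSeries.UBB, StratumAxis.TOTAL, ALL_LEVEL),
    (DoseSeries.UBB, StratumAxis.SEX, "M"),
    (DoseSeries.UBB, StratumAxis.SEX, "F"),
)
_AGE_COLS = tuple(
    (series, StratumAxis.AGE, band)
    for series in (DoseSeries.CPS, DoseSeries.UBB)
    for band in ("0-17", "18-49", "50-64", "65+")
)
_MANU_COLS = (
    (DoseSeries.ALOD, StratumAxis.MANUFACTURER, "PFIZER_BIONTECH"),
    (DoseSeries.ALOD, StratumAxis.MANUFACTURER, "MODERNA"),
    (DoseSeries.ALOD, StratumAxis.MANUFACTURER, "JANSSEN"),
    (DoseSeries.UBB, StratumAxis.MANUFACTURER, "PFIZER_BIONTECH"),
    (DoseSeries.UBB, StratumAxis.MANUFACTURER, "MODERNA"),
)

# Cell encoding: count|pct|ir as printed (no thousands separators); "0||0"
# is a cell printed as a bare zero. Rows are group<TAB>cell<TAB>cell...
_SEX_CELLS = """\
Hearing loss\t4319|4.05|1.906\t1759|5.46|1.629\t2560|3.44|2.158\t19|64.86|0.352\t70|5.3|0.278\t126|4.65|0.413
Tinnitus (Ringing in the ears)\t12338|11.57|5.445\t4960|15.41|4.593\t7378|9.91|6.221\t381|9.45|0.684\t146|11.05|0.579\t235|8.67|0.771
Ear infections (Otitis Media)\t563|0.53|0.248\t187|0.58|0.173\t376|0.5|0.317\t81|2.01|0.145\t24|1.82|0.095\t57|2.1|0.187
Meniere’s disease\t82|0.08|0.036\t25|0.08|0.023\t57|0.08|0.048\t3|0.07|0.005\t1|0.08|0.004\t2|0.07|0.007
Vestibular neuronitis\t98|0.09|0.043\t35|0.11|0.032\t63|0.08|0.053\t11|0.27|0.02\t4|0.3|0.016\t7|0.26|0.023
Dizziness or vertigo\t71255|66.81|31.446\t20126|62.53|18.637\t51129|68.66|43.108\t1610|39.94|2.89\t483|36.56|1.915\t1127|41.59|3.697
Sinusitis\t1333|1.25|0.588\t346|1.07|0.32\t987|1.33|0.832\t270|6.7|0.485\t80|6.06|0.317\t190|7.01|0.623
Rhinitis (Allergic and Non-allergic)\t126|0.12|0.056\t49|0.15|0.045\t77|0.1|0.065\t8|0.2|0.014\t2|0.15|0.008\t6|0.22|0.02
Epistaxis\t2085|1.95|0.92\t700|2.17|0.648\t1385|1.86|1.168\t45|1.12|0.081\t15|1.14|0.059\t30|1.11|0.098
Anosmia\t3652|3.42|1.612\t1237|3.84|1.146\t2415|3.24|2.036\t227|5.63|0.408\t64|4.84|0.254\t163|6.01|0.535
Nasal polyps\t15|0.01|0.007\t7|0.02|0.006\t8|0.01|0.007\t2|0.05|0.004\t1|0.08|0.004\t1|0.04|0.003
Snoring or difficulty breathing through the nose and sleep apnea\t494|0.46|0.218\t284|0.88|0.263\t210|0.28|0.177\t152|3.77|0.273\t84|6.36|0.333\t68|2.51|0.223
Allergies\t5983|5.61|2.64\t1219|3.79|1.129\t4764|6.4|4.017\t213|5.28|0.382\t58|4.39|0.23\t155|5.72|0.508
Tonsillitis\t73|0.07|0.032\t20|0.06|0.019\t53|0.07|0.045\t4|0.1|0.007\t1|0.08|0.004\t3|0.11|0.01
Laryngitis\t135|0.13|0.06\t23|0.07|0.021\t112|0.15|0.094\t54|1.34|0.097\t11|0.83|0.044\t43|1.59|0.141
Vocal cord polyps and nodules\t27|0.03|0.012\t6|0.02|0.006\t21|0.03|0.018\t0||0\t0||0\t0||0
Laryngopharyngeal reflux (acid reflux)\t337|0.32|0.149\t43|0.13|0.04\t294|0.39|0.248\t21|0.52|0.038\t6|0.45|0.024\t15|0.55|0.049
Epiglottitis\t8|0.01|0.004\t3|0.01|0.003\t5|0.01|0.004\t0||0\t0||0\t0||0
Pharyngitis\t3730|3.5|1.646\t1159|3.6|1.073\t2571|3.45|2.168\t753|18.68|1.352\t271|20.51|1.075\t482|17.79|1.581
ANY\t106653||47.068\t32188||29.807\t74465||62.783\t4031||7.237\t1321||5.238\t2710||8.89
"""

_SEX_SAMPLES = (226593618, 107987092, 118606526, 55703085, 25218543, 30484542)

_AGE_CELLS = """\
Hearing loss\t155|3.79|0.692\t429|2.94|0.437\t885|4.53|1.678\t804|5.01|1.576\t3|1.85|0.098\t17|6.32|0.111\t36|6.37|0.264\t79|4.83|0.338
Tinnitus (Ringing in the ears)\t166|4.06|0.741\t724|4.96|0.738\t3384|17.33|6.417\t2056|12.8|4.029\t9|5.56|0.294\t12|4.46|0.078\t81|14.34|0.593\t109|6.67|0.466
Ear infections (Otitis Media)\t27|0.66|0.121\t49|0.34|0.05\t98|0.5|0.186\t76|0.47|0.149\t5|3.09|0.163\t7|2.6|0.046\t21|3.72|0.154\t26|1.59|0.111
Meniere’s disease\t1|0.02|0.004\t2|0.01|0.002\t19|0.1|0.036\t20|0.12|0.039\t0||0\t1|0.37|0.007\t0||0\t2|0.12|0.009
Vestibular neuronitis\t2|0.05|0.009\t10|0.07|0.01\t24|0.12|0.046\t15|0.09|0.029\t1|0.62|0.033\t1|0.37|0.007\t2|0.35|0.015\t6|0.37|0.026
Dizziness or vertigo\t3291|80.5|14.695\t11582|79.32|11.799\t11978|61.33|22.715\t9849|61.33|19.3\t120|74.07|3.915\t159|59.11|1.039\t217|38.41|1.589\t537|32.86|2.294
Sinusitis\t21|0.51|0.094\t76|0.52|0.077\t265|1.36|0.503\t284|1.77|0.557\t3|1.85|0.098\t5|1.86|0.033\t32|5.66|0.234\t132|8.08|0.564
Rhinitis (Allergic and Non-allergic)\t2|0.05|0.009\t13|0.09|0.013\t24|0.12|0.046\t26|0.16|0.051\t0||0\t2|0.74|0.013\t2|0.35|0.015\t3|0.18|0.013
Epistaxis\t127|3.11|0.567\t247|1.69|0.252\t333|1.71|0.631\t348|2.17|0.682\t5|3.09|0.163\t4|1.49|0.026\t4|0.71|0.029\t18|1.1|0.077
Anosmia\t53|1.3|0.237\t372|2.55|0.379\t753|3.86|1.428\t599|3.73|1.174\t0||0\t4|1.49|0.026\t39|6.9|0.286\t98|6|0.419
Nasal polyps\t0||0\t2|0.01|0.002\t3|0.02|0.006\t4|0.02|0.008\t0||0\t0||0\t1|0.18|0.007\t1|0.06|0.004
Snoring or difficulty breathing through the nose and sleep apnea\t8|0.2|0.036\t36|0.25|0.037\t64|0.33|0.121\t131|0.82|0.257\t1|0.62|0.033\t5|1.86|0.033\t21|3.72|0.154\t71|4.35|0.303
Allergies\t147|3.6|0.656\t664|4.55|0.676\t963|4.93|1.826\t998|6.21|1.956\t7|4.32|0.228\t34|12.64|0.222\t33|5.84|0.242\t67|4.1|0.286
Tonsillitis\t3|0.07|0.013\t22|0.15|0.022\t11|0.06|0.021\t6|0.04|0.012\t0||0\t2|0.74|0.013\t0||0\t0||0
Laryngitis\t1|0.02|0.004\t10|0.07|0.01\t36|0.18|0.068\t28|0.17|0.055\t0||0\t3|1.12|0.02\t8|1.42|0.059\t32|1.96|0.137
Vocal cord polyps and nodules\t0||0\t1|0.01|0.001\t10|0.05|0.019\t6|0.04|0.012\t0||0\t0||0\t0||0\t0||0
Laryngopharyngeal reflux (acid reflux)\t3|0.07|0.013\t26|0.18|0.026\t83|0.43|0.157\t39|0.24|0.076\t0||0\t1|0.37|0.007\t1|0.18|0.007\t9|0.55|0.038
Epiglottitis\t0||0\t1|0.01|0.001\t2|0.01|0.004\t1|0.01|0.002\t0||0\t0||0\t0||0\t0||0
Pharyngitis\t81|1.98|0.362\t335|2.29|0.341\t594|3.04|1.126\t768|4.78|1.505\t8|4.94|0.261\t12|4.46|0.078\t67|11.86|0.491\t444|27.17|1.897
ANY\t4088||18.253\t14601||14.875\t19529||37.035\t16058||31.467\t162||5.285\t269||1.758\t565||4.138\t1634||6.981
"""

_AGE_SAMPLES = (22396020, 98160420, 52731727, 51031000, 3065181, 15303884, 13654874, 23407228)

_MANU_CELLS = """\
Hearing loss\t3391|4.62|2.222\t2455|4.23|2.543\t464|3.43|5.871\t113|4.76|0.319\t85|4.96|0.423
Tinnitus (Ringing in the ears)\t9308|12.69|6.100\t7049|12.14|7.303\t1516|11.2|19.182\t226|9.52|0.637\t168|9.8|0.837
Ear infections (Otitis Media)\t453|0.62|0.297\t345|0.59|0.357\t56|0.41|0.709\t51|2.15|0.144\t37|2.16|0.184
Meniere’s disease\t61|0.08|0.040\t50|0.09|0.052\t7|0.05|0.089\t2|0.08|0.006\t1|0.06|0.005
Vestibular neuronitis\t89|0.12|0.058\t66|0.11|0.068\t5|0.04|0.063\t6|0.25|0.017\t5|0.29|0.025
Dizziness or vertigo\t46290|63.09|30.336\t36646|63.14|37.964\t9579|70.79|121.202\t961|40.5|2.709\t668|38.95|3.328
Sinusitis\t1029|1.4|0.674\t941|1.62|0.975\t165|1.22|2.088\t154|6.49|0.434\t117|6.82|0.583
Rhinitis (Allergic and Non-allergic)\t91|0.12|0.060\t83|0.14|0.086\t9|0.07|0.114\t4|0.17|0.011\t4|0.23|0.020
Epistaxis\t1495|2.04|0.980\t1072|1.85|1.111\t336|2.48|4.251\t25|1.05|0.070\t20|1.17|0.100
Anosmia\t2919|3.98|1.913\t2032|3.5|2.105\t416|3.07|5.264\t128|5.39|0.361\t101|5.89|0.503
Nasal polyps\t8|0.01|0.005\t6|0.01|0.006\t3|0.02|0.038\t1|0.04|0.003\t1|0.06|0.005
Snoring or difficulty breathing through the nose and sleep apnea\t568|0.77|0.372\t357|0.62|0.370\t58|0.43|0.734\t121|5.1|0.341\t31|1.81|0.154
Allergies\t4134|5.63|2.709\t3918|6.75|4.059\t439|3.24|5.555\t126|5.31|0.355\t91|5.31|0.453
Tonsillitis\t50|0.07|0.033\t36|0.06|0.037\t8|0.06|0.101\t3|0.13|0.008\t1|0.06|0.005
Laryngitis\t135|0.18|0.088\t109|0.19|0.113\t15|0.11|0.190\t31|1.31|0.087\t24|1.4|0.120
Vocal cord polyps and nodules\t29|0.04|0.019\t13|0.02|0.013\t3|0.02|0.038\t0||0.000\t0||0.000
Laryngopharyngeal reflux (acid reflux)\t235|0.32|0.154\t193|0.33|0.200\t22|0.16|0.278\t13|0.55|0.037\t8|0.47|0.040
Epiglottitis\t6|0.01|0.004\t7|0.01|0.007\t2|0.01|0.025\t0||0.000\t0||0.000
Pharyngitis\t3076|4.19|2.016\t2663|4.59|2.759\t429|3.17|5.428\t408|17.19|1.150\t353|20.58|1.759
ANY\t73367||48.081\t58041||60.129\t13532||171.218\t2373||6.689\t1715||8.544
"""

_MANU_SAMPLES = (152590827, 96527417, 7903364, 35476628, 20072000)

#: Cells whose printed count contradicts the printed rate/share in the same
#: row (typesetting artifacts in the source); excluded from replay checks.
MISPRINT_CELLS: frozenset[tuple[str, DoseSeries, StratumAxis, str]] = frozenset(
    {
        # count printed 19 but share 64.86% and IR 0.352 imply ~196 (M+F = 196)
        ("Hearing loss", DoseSeries.UBB, StratumAxis.TOTAL, ALL_LEVEL),
    }
)

#: PRR results for the completed-primary-series corpus: group -> (m, PRR, CI low, CI high).
#: The background totals behind them were not published, so these support
#: qualitative checks only.
REFERENCE_PRR: dict[str, tuple[int, float, float, float]] = {
    "Hearing loss": (4319, 1.554, 1.487, 1.625),
    "Tinnitus (Ringing in the ears)": (12338, 2.343, 2.275, 2.413),
    "Ear infections (Otitis Media)": (563, 0.227, 0.207, 0.248),
    "Meniere’s disease": (82, 1.945, 1.382, 2.736),
    "Vestibular neuronitis": (98, 1.217, 0.924, 1.603),
    "Dizziness or vertigo": (71255, 1.629, 1.612, 1.647),
    "Sinusitis": (1333, 0.832, 0.777, 0.891),
    "Rhinitis (Allergic and Non-allergic)": (126, 0.056, 0.047, 0.067),
    "Epistaxis": (2085, 1.605, 1.506, 1.712),
    "Anosmia": (3652, 3.167, 2.983, 3.363),
    "Nasal polyps": (15, 1.956, 0.879, 4.355),
    "Snoring or difficulty breathing through the nose and sleep apnea": (494, 0.205, 0.186, 0.225),
    "Allergies": (5983, 0.251, 0.244, 0.258),
    "Tonsillitis": (73, 0.491, 0.375, 0.642),
    "Laryngitis": (135, 0.332, 0.275, 0.401),
    "Vocal cord polyps and nodules": (27, 1.101, 0.659, 1.837),
    "Laryngopharyngeal reflux (acid reflux)": (337, 2.632, 2.187, 3.168),
    "Epiglottitis": (8, 0.348, 0.159, 0.759),
    "Pharyngitis": (3730, 0.573, 0.551, 0.596),
}

#: Manufacturer-attributed report totals of the full corpus (all doses);
#: shares printed as 50.6% / 40.0% / 9.3%.
MANUFACTURER_REPORT_TOTALS: dict[str, int] = {
    "PFIZER_BIONTECH": 73367,
    "MODERNA": 58041,
    "JANSSEN": 13532,
}


@dataclass(frozen=True)
class ReferenceCell:
    """One printed table cell: the count plus the printed share and rate strings."""

    group: str
    series: DoseSeries
    axis: StratumAxis
    level: str
    count: int
    pct_printed: str | None
    ir_printed: str | None
    misprint: bool = False


def _parse_block(block: str, cols) -> list[ReferenceCell]:
    cells: list[ReferenceCell] = []
    for line in block.strip("\n").split("\n"):
        fields = line.split("\t")
        group, raw_cells = fields[0], fields[1:]
        assert len(raw_cells) == len(cols), f"row {group!r}: {len(raw_cells)} cells"
        for raw, (series, axis, level) in zip(raw_cells, cols):
            count_s, pct_s, ir_s = raw.split("|")
            cells.append(
                ReferenceCell(
                    group=group,
                    series=series,
                    axis=axis,
                    level=level,
                    count=int(count_s),
                    pct_printed=pct_s or None,
                    ir_printed=ir_s or None,
                    misprint=(group, series, axis, level) in MISPRINT_CELLS,
                )
            )
    return cells


def reference_cells() -> list[ReferenceCell]:
    """All printed (group x stratum) cells of the three incidence tables."""
    return (
        _parse_block(_SEX_CELLS, _SEX_COLS)
        + _parse_block(_AGE_CELLS, _AGE_COLS)
        + _parse_block(_MANU_CELLS, _MANU_COLS)
    )


def reference_denominators() -> DenominatorTable:
    """The published vaccinated-population sample sizes as a DenominatorTable."""
    table = DenominatorTable()
    for cols, samples in (
        (_SEX_COLS, _SEX_SAMPLES),
        (_AGE_COLS, _AGE_SAMPLES),
        (_MANU_COLS, _MANU_SAMPLES),
    ):
        for (series, axis, level), persons in zip(cols, samples):
            table.add(series, axis, level, persons)
    return table


def reference_any_counts() -> dict[tuple[DoseSeries, StratumAxis, str], int]:
    """Total otolaryngologic report count per stratum column (the 'Any' row)."""
    return {
        (c.series, c.axis, c.level): c.count
        for c in reference_cells()
        if c.group == ANY_GROUP
    }


def replay_fixture_tables() -> tuple[pd.DataFrame, DenominatorTable]:
    """Counts-and-sample-sizes replay fixture for exact reproduction checks.

    Returns a DataFrame with columns (group, series, axis, level, count) —
    printed counts only, no derived quantities — and the matching
    denominator table.
    """
    frame = pd.DataFrame(
        [
            {
                "group": c.group,
                "series": c.series.value,
                "axis": c.axis.value,
                "level": c.level,
                "count": c.count,
            }
            for c in reference_cells()
        ]
    )
    return frame, reference_denominators()
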