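"""Stratified counts, shares and incidence rates, including the published-table replay."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otosignal import (
    DenominatorTable,
    DoseSeries,
    GroupedReport,
    PTGroupMap,
    StratumAxis,
    build_table,
    count_reports,
    incidence_rate,
    percent_share,
)
from otosignal.errors import MissingDenominatorError, UndefinedShareError
from otosignal.models import ALL_LEVEL, ANY_GROUP
from otosignal import refdata

from test_pt_grouping import make_report


def grouped(rid, groups, sex="F", age=40.0, series=DoseSeries.CPS, manu="MODERNA"):
    from otosignal.models import AEReport, Manufacturer, Sex

    report = AEReport(
        report_id=rid,
        vaccine_types=frozenset({"COVID19"}),
        manufacturer=Manufacturer(manu),
        dose_series=series,
        sex=Sex(sex),
        age_years=age,
        preferred_terms=frozenset({"x"}),
    )
    return GroupedReport(report=report, groups=frozenset(groups))


class TestScalarOps:
    @pytest.mark.parametrize(
        "count,den,expected",
        [
            (106_653, 226_593_618, 47.068),  # total otolaryngologic rate, CPS
            (12_338, 226_593_618, 5.445),  # tinnitus, CPS
            (13_532, 7_903_364, 171.218),  # any-event rate, Janssen at-least-one-dose
            (0, 1000, 0.0),
        ],
    )
    def test_incidence_rate_reference_values(self, count, den, expected):
        assert round(incidence_rate(count, den), 3) == expected

    def test_incidence_rate_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            incidence_rate(10, 0)

    @given(
        m=st.integers(0, 10_000), d=st.integers(1, 10**9), k=st.integers(1, 50)
    )
    @settings(max_examples=100, deadline=None)
    def test_incidence_rate_scale_invariant(self, m, d, k):
        assert incidence_rate(k * m, k * d) == pytest.approx(incidence_rate(m, d))

    @pytest.mark.parametrize(
        "count,total,decimals,expected",
        [
            (71_255, 106_653, 2, 66.81),  # dizziness share of CPS reports
            (73_367, 144_940, 1, 50.6),  # Pfizer share of manufacturer-attributed reports
            (42, 42, 1, 100.0),
        ],
    )
    def test_percent_share_reference_values(self, count, total, decimals, expected):
        assert round(percent_share(count, total), decimals) == expected

    def test_percent_share_of_zero_total_is_undefined(self):
        with pytest.raises(UndefinedShareError):
            percent_share(1, 0)


class TestCountReports:
    def test_empty_input_gives_empty_counts(self):
        assert count_reports([], DoseSeries.CPS, StratumAxis.SEX) == {}

    def test_sex_counts_and_any_row(self):
        g = [
            grouped("1", ["Tinnitus (Ringing in the ears)"], sex="F"),
            grouped("2", ["Tinnitus (Ringing in the ears)"], sex="F"),
            grouped("3", ["Tinnitus (Ringing in the ears)"], sex="M"),
        ]
        c = count_reports(g, DoseSeries.CPS, StratumAxis.SEX)
        assert c[("Tinnitus (Ringing in the ears)", "F")] == 2
        assert c[("Tinnitus (Ringing in the ears)", "M")] == 1
        total = count_reports(g, DoseSeries.CPS, StratumAxis.TOTAL)
        assert total[("Tinnitus (Ringing in the ears)", ALL_LEVEL)] == 3
        assert total[(ANY_GROUP, ALL_LEVEL)] == 3

    def test_multi_group_report_counts_once_per_group_and_once_in_any(self):
        g = [grouped("1", ["Anosmia", "Dizziness or vertigo"])]
        c = count_reports(g, DoseSeries.CPS, StratumAxis.TOTAL)
        assert c[(ANY_GROUP, ALL_LEVEL)] == 1
        assert c[("Anosmia", ALL_LEVEL)] == 1
        assert c[("Dizziness or vertigo", ALL_LEVEL)] == 1

    def test_unknown_level_excluded_from_levels_but_kept_in_total(self):
        g = [
            grouped("1", ["Anosmia"], sex="UNKNOWN"),
            grouped("2", ["Anosmia"], sex="F"),
        ]
        sex_counts = count_reports(g, DoseSeries.CPS, StratumAxis.SEX)
        assert sex_counts[("Anosmia", "F")] == 1
        assert ("Anosmia", "UNKNOWN") not in sex_counts
        total = count_reports(g, DoseSeries.CPS, StratumAxis.TOTAL)
        assert total[("Anosmia", ALL_LEVEL)] == 2

    def test_level_sums_match_total_without_missingness(self):
        g = [
            grouped(str(i), ["Anosmia"], sex="F" if i % 2 else "M", age=10.0 * (i % 9))
            for i in range(20)
        ]
        for axis in (StratumAxis.SEX, StratumAxis.AGE):
            by_level = count_reports(g, DoseSeries.CPS, axis)
            level_sum = sum(
                v for (grp, _), v in by_level.items() if grp == "Anosmia"
            )
            total = count_reports(g, DoseSeries.CPS, StratumAxis.TOTAL)
            assert level_sum == total[("Anosmia", ALL_LEVEL)]


class TestBuildTable:
    def test_single_report_corpus(self):
        den = DenominatorTable()
        den.add(DoseSeries.CPS, StratumAxis.TOTAL, ALL_LEVEL, 200_000)
        table = build_table(
            [grouped("1", ["Anosmia"])], den, DoseSeries.CPS, [StratumAxis.TOTAL]
        )
        row = table.row("Anosmia", "CPS", "TOTAL", ALL_LEVEL)
        assert row["count"] == 1
        assert row["ir_per_100k"] == pytest.approx(1e5 / 200_000)

    def test_uniform_four_group_corpus(self):
        # 100 reports spread evenly over 4 groups, denominator 1e6 -> IR 2.5 each
        groups = ["A", "B", "C", "D"]
        g = [grouped(str(i), [groups[i % 4]]) for i in range(100)]
        den = DenominatorTable()
        den.add(DoseSeries.CPS, StratumAxis.TOTAL, ALL_LEVEL, 1_000_000)
        table = build_table(g, den, DoseSeries.CPS, [StratumAxis.TOTAL], groups=groups)
        for grp in groups:
            assert table.row(grp, "CPS", "TOTAL", ALL_LEVEL)["ir_per_100k"] == pytest.approx(2.5)
            assert table.row(grp, "CPS", "TOTAL", ALL_LEVEL)["pct"] == pytest.approx(25.0)

    def test_manufacturer_axis_uses_alod_denominators_for_cps(self):
        den = refdata.reference_denominators()
        g = [grouped("1", ["Anosmia"], manu="JANSSEN")]
        table = build_table(g, den, DoseSeries.CPS, [StratumAxis.MANUFACTURER])
        row = table.row("Anosmia", "CPS", "MANUFACTURER", "JANSSEN")
        assert row["ir_per_100k"] == pytest.approx(1e5 / 7_903_364)

    def test_ubb_manufacturer_levels_cover_only_published_denominators(self):
        den = refdata.reference_denominators()
        g = [grouped("1", ["Anosmia"], series=DoseSeries.UBB, manu="MODERNA")]
        table = build_table(g, den, DoseSeries.UBB, [StratumAxis.MANUFACTURER])
        levels = set(table.frame["level"])
        assert levels == {"PFIZER_BIONTECH", "MODERNA"}

    def test_missing_denominator_is_a_structured_error(self):
        den = DenominatorTable()
        with pytest.raises(MissingDenominatorError):
            build_table(
                [grouped("1", ["Anosmia"])], den, DoseSeries.CPS, [StratumAxis.TOTAL]
            )


def printed_tolerance(printed: str) -> float:
    """Half a unit in the last printed decimal place."""
    if "." not in printed:
        return 0.5
    return 0.5 * 10 ** -len(printed.split(".")[1])


def test_published_table_cells_reproduce_from_counts_and_sample_sizes():
    """Every printed IR and % cell (bar flagged misprints) follows exactly
    from its printed count, the stratum sample size and the stratum total."""
    dens = refdata.reference_denominators()
    any_counts = refdata.reference_any_counts()
    checked = 0
    for cell in refdata.reference_cells():
        if cell.misprint:
            continue
        den = dens.lookup(cell.series, cell.axis, cell.level)
        if cell.ir_printed is not None:
            ir = incidence_rate(cell.count, den)
            assert abs(ir - float(cell.ir_printed)) <= printed_tolerance(cell.ir_printed) + 1e-12, cell
            checked += 1
        if cell.pct_printed is not None:
            pct = percent_share(cell.count, any_counts[(cell.series, cell.axis, cell.level)])
            assert abs(pct - float(cell.pct_printed)) <= printed_tolerance(cell.pct_printed) + 1e-12, cell
            checked += 1
    assert checked > 700
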