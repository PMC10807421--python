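"""Reading and writing the three-file report layout and the side tables."""
import math

import pandas as pd
import pytest

from otosignal import (
    DenominatorTable,
    DoseSeries,
    Manufacturer,
    Sex,
    StratifiedCountTable,
    StratumAxis,
    read_denominators,
    read_group_map,
    read_reports,
    read_result_table,
    write_result_table,
)
from otosignal.errors import (
    MissingColumnError,
    MissingDenominatorError,
    MappingConfigError,
    VaersLoadError,
)
from otosignal.refdata import REFERENCE_GROUPS
from otosignal.vaers_io import default_group_map, format_p

from conftest import write_corpus


class TestReadReports:
    def test_symptom_rows_merge_by_set_union(self, five_report_corpus):
        reports = {r.report_id: r for r in read_reports(*five_report_corpus)}
        assert reports["1"].preferred_terms == frozenset({"Tinnitus", "Vertigo"})

    def test_filter_excludes_other_vaccine_types(self, five_report_corpus):
        reports = read_reports(*five_report_corpus, vaccine_type_filter={"COVID19"})
        assert sorted(r.report_id for r in reports) == ["1", "2"]

    def test_filter_with_no_matching_type_yields_empty(self, tmp_path):
        files = write_corpus(
            tmp_path, ["9,50,F"], ["9,FLU3,OTHER MFR,1"], ["9,Tinnitus,,,,"]
        )
        assert read_reports(*files, vaccine_type_filter={"COVID19"}) == []

    def test_demographics_and_series_assignment(self, five_report_corpus):
        reports = {r.report_id: r for r in read_reports(*five_report_corpus)}
        r1 = reports["1"]
        assert r1.sex == Sex.F
        assert r1.age_years == 45.0
        assert r1.manufacturer == Manufacturer.PFIZER_BIONTECH
        assert r1.dose_series == DoseSeries.CPS

    def test_missing_sex_and_age_become_unknown(self, five_report_corpus):
        reports = {
            r.report_id: r
            for r in read_reports(*five_report_corpus, vaccine_type_filter=None)
        }
        assert reports["4"].sex == Sex.UNKNOWN
        assert reports["4"].age_years is None

    def test_bivalent_record_supersedes_primary(self, tmp_path):
        files = write_corpus(
            tmp_path,
            ["7,33,F"],
            ["7,COVID19,MODERNA,2", "7,COVID19-2,MODERNA,3"],
            ["7,Tinnitus,,,,"],
        )
        (report,) = read_reports(*files)
        assert report.dose_series == DoseSeries.UBB

    def test_missing_required_column_names_file_and_column(self, tmp_path):
        data = tmp_path / "DATA.csv"
        data.write_text("VAERS_ID,SEX\n1,F\n")
        vax = tmp_path / "VAX.csv"
        vax.write_text("VAERS_ID,VAX_TYPE,VAX_MANU,VAX_DOSE_SERIES\n1,COVID19,MODERNA,1\n")
        symptoms = tmp_path / "SYMPTOMS.csv"
        symptoms.write_text("VAERS_ID,SYMPTOM1\n1,Tinnitus\n")
        with pytest.raises(MissingColumnError) as err:
            read_reports(data, vax, symptoms)
        assert "AGE_YRS" in str(err.value)
        assert "DATA.csv" in str(err.value)

    def test_duplicate_demographics_first_record_wins(self, tmp_path, caplog):
        files = write_corpus(
            tmp_path,
            ["1,45,F", "1,60,M"],
            ["1,COVID19,MODERNA,1"],
            ["1,Tinnitus,,,,"],
        )
        with caplog.at_level("WARNING"):
            (report,) = read_reports(*files)
        assert report.sex == Sex.F and report.age_years == 45.0
        assert any("duplicate" in m for m in caplog.messages)

    def test_row_order_insensitive(self, tmp_path):
        rows = dict(
            data_rows=["1,45,F", "2,60,M"],
            vax_rows=["1,COVID19,MODERNA,1", "2,COVID19,PFIZER\\BIONTECH,2"],
            symptom_rows=["1,Tinnitus,,,,", "2,Vertigo,,,,", "1,Anosmia,,,,"],
        )
        a = read_reports(*write_corpus(tmp_path / "fwd", **rows))
        rows_rev = {k: list(reversed(v)) for k, v in rows.items()}
        b = read_reports(*write_corpus(tmp_path / "rev", **rows_rev))
        assert sorted(a, key=lambda r: r.report_id) == sorted(b, key=lambda r: r.report_id)

    def test_enlarging_filter_never_loses_reports(self, five_report_corpus):
        small = read_reports(*five_report_corpus, vaccine_type_filter={"COVID19"})
        big = read_reports(
            *five_report_corpus, vaccine_type_filter={"COVID19", "FLU3", "FLU4"}
        )
        assert {r.report_id for r in small} <= {r.report_id for r in big}


class TestReadDenominators:
    def test_parses_plain_and_comma_separated_counts(self, denominator_csv):
        table = read_denominators(denominator_csv)
        assert table.lookup(DoseSeries.CPS, StratumAxis.TOTAL, "ALL") == 226_593_618
        assert table.lookup(DoseSeries.UBB, StratumAxis.TOTAL, "ALL") == 55_703_085

    def test_empty_table_lookup_raises_missing_denominator(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("series,axis,level,persons\n")
        table = read_denominators(path)
        assert len(table) == 0
        with pytest.raises(MissingDenominatorError):
            table.lookup(DoseSeries.CPS, StratumAxis.TOTAL, "ALL")

    @pytest.mark.parametrize(
        "row", ["CPS,TOTAL,ALL,-5", "CPS,TOTAL,ALL,abc"], ids=["negative", "unparseable"]
    )
    def test_bad_person_counts_are_load_errors(self, tmp_path, row):
        path = tmp_path / "den.csv"
        path.write_text(f"series,axis,level,persons\n{row}\n")
        with pytest.raises(VaersLoadError):
            read_denominators(path)

    def test_duplicate_stratum_is_load_error(self, tmp_path):
        path = tmp_path / "den.csv"
        path.write_text("series,axis,level,persons\nCPS,SEX,M,10\nCPS,SEX,M,20\n")
        with pytest.raises(VaersLoadError):
            read_denominators(path)

    def test_level_sum_exceeding_total_rejected(self):
        table = DenominatorTable()
        table.add(DoseSeries.CPS, StratumAxis.TOTAL, "ALL", 100)
        table.add(DoseSeries.CPS, StratumAxis.SEX, "M", 80)
        table.add(DoseSeries.CPS, StratumAxis.SEX, "F", 30)
        with pytest.raises(ValueError):
            table.check_consistency()


class TestGroupMap:
    def test_single_group_single_pt(self, tmp_path):
        path = tmp_path / "g.yaml"
        path.write_text("Tinnitus (Ringing in the ears):\n  - Tinnitus\n")
        gmap = read_group_map(path)
        assert len(gmap) == 1
        assert gmap.mapping["Tinnitus"] == "Tinnitus (Ringing in the ears)"

    def test_pt_under_two_groups_is_config_error(self, tmp_path):
        path = tmp_path / "g.yaml"
        path.write_text("A:\n  - Tinnitus\nB:\n  - Tinnitus\n")
        with pytest.raises(MappingConfigError) as err:
            read_group_map(path)
        assert "Tinnitus" in str(err.value)

    def test_shipped_default_has_the_19_canonical_groups(self, shipped_map):
        assert shipped_map.groups == REFERENCE_GROUPS
        assert len(shipped_map.groups) == 19


class TestResultTables:
    @staticmethod
    def _table():
        return StratifiedCountTable(
            pd.DataFrame(
                [
                    {
                        "group": "Hearing loss", "series": "CPS", "axis": "TOTAL",
                        "level": "ALL", "count": 4319, "pct": 4.05,
                        "ir_per_100k": 4319 / 226_593_618 * 1e5, "p_value": 2e-5,
                    },
                    {
                        "group": "Anosmia", "series": "CPS", "axis": "SEX",
                        "level": "F", "count": 2415, "pct": 3.24,
                        "ir_per_100k": 2.036, "p_value": 0.049,
                    },
                ]
            )
        )

    def test_round_trip_preserves_counts_and_keys(self, tmp_path):
        path = tmp_path / "out.tsv"
        table = self._table()
        write_result_table(table, path)
        back = read_result_table(path)
        key_cols = ["group", "series", "axis", "level", "count"]
        pd.testing.assert_frame_equal(back.frame[key_cols], table.frame[key_cols])

    def test_formatting_matches_display_conventions(self, tmp_path):
        path = tmp_path / "out.tsv"
        write_result_table(self._table(), path)
        text = path.read_text()
        assert "\t1.906\t" in text  # IR at 3 decimals
        assert "\t4.05\t" in text  # share at 2 decimals
        assert "<0.001" in text  # tiny p-values
        assert "\t0.049" in text

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_result_table(StratifiedCountTable(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "group"


def test_format_p_convention():
    assert format_p(0.0005) == "<0.001"
    assert format_p(0.0499) == "0.050"
    assert format_p(float("nan")) == ""
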