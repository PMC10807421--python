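"""Shared fixtures: tiny hand-written report corpora and mapping configs."""
from __future__ import annotations

import textwrap

import pytest

from otosignal import PTGroupMap, default_group_map


@pytest.fixture(scope="session")
def shipped_map() -> PTGroupMap:
    return default_group_map()


@pytest.fixture
def tiny_map() -> PTGroupMap:
    return PTGroupMap.from_group_lists(
        {
            "Tinnitus (Ringing in the ears)": ["Tinnitus", "Tinnitus aggravated"],
            "Dizziness or vertigo": ["Vertigo", "Dizziness"],
            "Anosmia": ["Anosmia"],
        }
    )


def write_corpus(tmp_path, data_rows, vax_rows, symptom_rows):
    """Write the three-file layout from lists of CSV body lines."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    data = tmp_path / "DATA.csv"
    vax = tmp_path / "VAX.csv"
    symptoms = tmp_path / "SYMPTOMS.csv"
    data.write_text("VAERS_ID,AGE_YRS,SEX\n" + "\n".join(data_rows) + "\n")
    vax.write_text(
        "VAERS_ID,VAX_TYPE,VAX_MANU,VAX_DOSE_SERIES\n" + "\n".join(vax_rows) + "\n"
    )
    symptoms.write_text(
        "VAERS_ID,SYMPTOM1,SYMPTOM2,SYMPTOM3,SYMPTOM4,SYMPTOM5\n"
        + "\n".join(symptom_rows)
        + "\n"
    )
    return data, vax, symptoms


@pytest.fixture
def five_report_corpus(tmp_path):
    """Five reports: two COVID19 (one with split symptom rows), three FLU."""
    return write_corpus(
        tmp_path,
        data_rows=[
            "1,45,F",
            "2,60,M",
            "3,30,F",
            "4,,",
            "5,71,M",
        ],
        vax_rows=[
            "1,COVID19,PFIZER\\BIONTECH,2",
            "2,COVID19,MODERNA,1",
            "3,FLU3,OTHER MFR,1",
            "4,FLU3,OTHER MFR,1",
            "5,FLU4,OTHER MFR,1",
        ],
        symptom_rows=[
            "1,Tinnitus,,,,",
            "1,Tinnitus,Vertigo,,,",
            "2,Anosmia,,,,",
            "3,Tinnitus,,,,",
            "4,Headache,,,,",
            "5,Vertigo,,,,",
        ],
    )


@pytest.fixture
def denominator_csv(tmp_path):
    path = tmp_path / "den.csv"
    path.write_text(
        textwrap.dedent(
            """\
            series,axis,level,persons
            CPS,TOTAL,ALL,226593618
            CPS,SEX,M,107987092
            CPS,SEX,F,118606526
            UBB,TOTAL,ALL,"55,703,085"
            """
        )
    )
    return path
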