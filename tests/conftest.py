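from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from faersignal import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from faersignal.ingest import Annotation


@pytest.fixture(scope="session")
def cohort():
    """A 5000-report default-condition cohort shared across tests (seed 42)."""
    cases, truth = synthetic.simulate(synthetic.SyntheticConfig(n_reports=5000, seed=42))
    return cases, truth


def write_quarter_files(directory: Path, tables: dict[str, list[str]]) -> None:
    """Write hand-crafted $-delimited tables (first line is the header)."""
    directory.mkdir(parents=True, exist_ok=True)
    for name, lines in tables.items():
        (directory / f"{name.upper()}.txt").write_text("\n".join(lines) + "\n")


TINY_QUARTER = {
    "demo": [
        "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$reporter_country$occp_cod",
        "101$10$20200115$20200110$34$YR$F$60$KG$US$MD",
        "201$20$20210301$$24$MON$M$154$LBS$CA$CN",
        "301$30$20210401$20210301$3$DEC$F$$$JP$PH",
        "401$40$20220101$$$$M$80$KG$US$OT",
        "501$50$20220301$20220215$61$YR$F$90$KG$DE$MD",
    ],
    "drug": [
        "primaryid$caseid$drug_seq$role_cod$drugname",
        "101$10$1$PS$ILARIS",
        "101$10$2$C$METHOTREXATE",
        "201$20$1$PS$IBUPROFEN",
        "301$30$1$C$canakinumab",
        "301$30$2$PS$PREDNISONE",
        "401$40$1$PS$Canakinumab injection",
        "501$50$1$SS$ILARIS",
    ],
    "reac": [
        "primaryid$caseid$pt",
        "101$10$Pneumonia",
        "101$10$Deafness",
        "201$20$Rash",
        "301$30$Pneumonia",
        "401$40$Headache",
        "501$50$Pneumonia",
    ],
    "outc": [
        "primaryid$caseid$outc_cod",
        "101$10$HO",
        "101$10$DE",
        "301$30$OT",
    ],
    "ther": [
        "primaryid$caseid$dsg_drug_seq$start_dt$end_dt",
        "101$10$1$20200101$",
        "501$50$1$20220201$",
    ],
}


@pytest.fixture()
def tiny_quarter(tmp_path: Path) -> Path:
    qdir = tmp_path / "q1"
    write_quarter_files(qdir, TINY_QUARTER)
    return qdir


@pytest.fixture()
def annotation() -> Annotation:
    return Annotation(
        pt_to_soc={
            "deafness": "Ear and labyrinth disorders",
            "pneumonia": "Respiratory, thoracic, and mediastinal disorders",
            "rash": "Skin and subcutaneous tissue disorders",
            "infection": "Infections and infestations",
            "gastroenteritis": "Infections and infestations",
            "appendicitis": "Infections and infestations",
            "varicella": "Infections and infestations",
            "headache": "Nervous system disorders",
        },
        dme_terms={"deafness"},
        ime_terms={"deafness", "pneumonia", "appendicitis"},
        evidence={"pneumonia": "++", "deafness": "-", "rash": "+"},
    )
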