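"""Ingestion of FAERS-style quarterly ASCII extracts.

FAERS quarters ship as ``$``-delimited text tables with a header line:
DEMO (one row per report version), DRUG, REAC, OUTC and THER (one row per
drug / reaction / outcome / therapy episode). Report versions share a
``caseid``; each version has its own ``primaryid``. This module parses
those tables, collapses versions to one report per case, normalizes units
(age to years, weight to kg), and attaches MedDRA PT->SOC and EMA DME/IME
annotations supplied by the user as TSVs.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawTables",
    "ReportCase",
    "Annotation",
    "PTAnnotation",
    "IngestLog",
    "read_quarter",
    "deduplicate",
    "normalize_case",
    "normalize_cases",
    "select_target_reports",
    "annotate",
]

TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther")
MANDATORY_TABLES = ("demo", "drug", "reac")

# FAERS age-unit codes -> multiplier to years
AGE_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8765.82,
}
LBS_TO_KG = 0.45359237

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "other_serious",  # congenital anomaly
    "RI": "other_serious",  # required intervention
    "OT": "other_serious",
}

SEX_CODES = {"F": "female", "M": "male"}

REPORTER_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
    "RN": "other_health_professional",
    "CN": "consumer",
}


@dataclass
class IngestLog:
    """Counters accumulated while parsing and normalizing."""

    rows_read: Counter = field(default_factory=Counter)
    rows_skipped: Counter = field(default_factory=Counter)
    warnings: Counter = field(default_factory=Counter)

    def merge(self, other: "IngestLog") -> None:
        self.rows_read.update(other.rows_read)
        self.rows_skipped.update(other.rows_skipped)
        self.warnings.update(other.warnings)


@dataclass
class RawTables:
    """The five FAERS tables as string-typed DataFrames (lower-case columns)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    log: IngestLog = field(default_factory=IngestLog)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_NAMES}

    def orphan_counts(self) -> dict[str, int]:
        """Child rows whose primaryid does not appear in DEMO."""
        known = set(self.demo["primaryid"]) if len(self.demo) else set()
        out = {}
        for name in ("drug", "reac", "outc", "ther"):
            t = self.table(name)
            out[name] = 0 if t.empty else int((~t["primaryid"].isin(known)).sum())
        return out


def _empty_table(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="string") for c in columns})


_DEFAULT_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "wt", "wt_cod", "reporter_country", "occp_cod"],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
}


def _read_dollar_file(path: Path, log: IngestLog, table: str) -> pd.DataFrame:
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        logger.warning("%s: empty file %s", table, path.name)
        log.warnings[f"{table}_empty_file"] += 1
        return _empty_table(_DEFAULT_COLUMNS[table])
    header = [c.strip().lower() for c in lines[0].split("$")]
    width = len(header)
    rows: list[list[str]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) != width:
            log.rows_skipped[table] += 1
            logger.warning("%s: skipping malformed row (%d fields, want %d)",
                           table, len(fields), width)
            continue
        rows.append([f.strip() for f in fields])
        log.rows_read[table] += 1
    df = pd.DataFrame(rows, columns=header, dtype="string")
    return df


def read_quarter(directory: str | Path, dialect: str = "faers") -> RawTables:
    """Parse one quarter directory of ``$``-delimited FAERS tables.

    Files are located case-insensitively by name prefix (``DEMO*``,
    ``DRUG*``, ...). DEMO/DRUG/REAC are mandatory; OUTC/THER default to
    empty tables when absent. Malformed rows (wrong field count) are
    skipped and counted in the returned ``log``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"quarter directory not found: {directory}")
    log = IngestLog()
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        matches = sorted(
            p for p in directory.iterdir()
            if p.is_file() and p.name.lower().startswith(name)
        )
        if not matches:
            if name in MANDATORY_TABLES:
                raise FileNotFoundError(
                    f"mandatory table {name.upper()} missing from {directory}"
                )
            tables[name] = _empty_table(_DEFAULT_COLUMNS[name])
            continue
        tables[name] = _read_dollar_file(matches[0], log, name)
    raw = RawTables(log=log, **tables)
    for child, n_orphan in raw.orphan_counts().items():
        if n_orphan:
            log.warnings[f"{child}_orphan_rows"] += n_orphan
    return raw


def concat_quarters(quarters: Sequence[RawTables]) -> RawTables:
    """Stack several quarters into one RawTables (before deduplication)."""
    log = IngestLog()
    merged = {}
    for name in TABLE_NAMES:
        merged[name] = pd.concat([q.table(name) for q in quarters], ignore_index=True)
    for q in quarters:
        log.merge(q.log)
    return RawTables(log=log, **merged)


def _numeric_id(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce").fillna(-1)


def deduplicate(raw: RawTables, strategy: str = "caseid-latest") -> RawTables:
    """Collapse report versions: at most one primaryid per case.

    ``caseid-latest`` (default, field practice): keep the version with the
    latest FDA receipt date, ties broken by the largest primaryid.
    ``primaryid-distinct``: only drop exact primaryid repeats.
    Child tables are filtered to the retained primaryids.
    """
    demo = raw.demo
    if demo.empty:
        return raw
    if strategy == "primaryid-distinct":
        kept = demo.drop_duplicates(subset="primaryid", keep="first")
    elif strategy == "caseid-latest":
        order = demo.assign(
            _fda=pd.to_numeric(demo.get("fda_dt"), errors="coerce").fillna(0),
            _pid=_numeric_id(demo["primaryid"]),
        ).sort_values(["_fda", "_pid"], kind="mergesort")
        kept = order.drop_duplicates(subset="caseid", keep="last")
        kept = kept.drop(columns=["_fda", "_pid"]).sort_index()
    else:
        raise ValueError(f"unknown dedup strategy {strategy!r}")
    keep_ids = set(kept["primaryid"])
    out = {"demo": kept.reset_index(drop=True)}
    for name in ("drug", "reac", "outc", "ther"):
        t = raw.table(name)
        out[name] = t[t["primaryid"].isin(keep_ids)].reset_index(drop=True)
    return RawTables(log=raw.log, **out)


@dataclass(frozen=True)
class ReportCase:
    """One deduplicated safety report in analysis-ready form."""

    primaryid: str
    caseid: str
    fda_date: _dt.date | None
    sex: str  # female / male / unknown
    age_years: float | None
    weight_kg: float | None
    country: str | None
    reporter: str  # consumer / physician / pharmacist / other_health_professional / unknown
    outcomes: frozenset[str]
    drugs: tuple[tuple[str, str], ...]  # (name, role) with role in PS/SS/C/I
    events: frozenset[str]  # distinct MedDRA PTs
    event_date: _dt.date | None = None
    therapy_start: _dt.date | None = None
    event_date_partial: bool = False
    therapy_start_partial: bool = False

    @property
    def serious(self) -> bool:
        return bool(self.outcomes)


def _parse_float(value, log: IngestLog, what: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        x = float(s)
    except ValueError:
        log.warnings[f"unparseable_{what}"] += 1
        return None
    if x < 0:
        log.warnings[f"negative_{what}"] += 1
        return None
    return x


def parse_faers_date(value, log: IngestLog | None = None) -> tuple[_dt.date | None, bool]:
    """Parse YYYYMMDD / YYYYMM / YYYY; returns (date, was_partial)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    s = str(value).strip()
    if not s or not s.isdigit():
        if s and log is not None:
            log.warnings["unparseable_date"] += 1
        return None, False
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), False
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:6]), 1), True
        if len(s) == 4:
            return _dt.date(int(s), 1, 1), True
    except ValueError:
        pass
    if log is not None:
        log.warnings["unparseable_date"] += 1
    return None, False


def _get(row: Mapping, key: str) -> str:
    v = row.get(key)
    if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v):
        return ""
    return str(v).strip()


def normalize_case(
    demo_row: Mapping,
    drug_rows: Iterable[Mapping] = (),
    reac_rows: Iterable[Mapping] = (),
    outc_rows: Iterable[Mapping] = (),
    ther_rows: Iterable[Mapping] = (),
    log: IngestLog | None = None,
) -> ReportCase:
    """Assemble one ReportCase from raw rows sharing a primaryid.

    Unit handling: age codes DEC/YR/MON/WK/DY/HR are converted to years,
    LBS to kg; anything unparseable degrades to missing with a warning
    counter rather than raising.
    """
    log = log if log is not None else IngestLog()
    pid = _get(demo_row, "primaryid")
    caseid = _get(demo_row, "caseid") or pid

    age = _parse_float(_get(demo_row, "age"), log, "age")
    age_cod = _get(demo_row, "age_cod").upper() or "YR"
    if age is not None:
        factor = AGE_TO_YEARS.get(age_cod)
        if factor is None:
            log.warnings["unknown_age_cod"] += 1
            age = None
        else:
            age *= factor

    wt = _parse_float(_get(demo_row, "wt"), log, "weight")
    wt_cod = _get(demo_row, "wt_cod").upper() or "KG"
    if wt is not None:
        if wt_cod in ("KG", "KGS"):
            pass
        elif wt_cod == "LBS":
            wt *= LBS_TO_KG
        else:
            log.warnings["unknown_wt_cod"] += 1
            wt = None

    sex = SEX_CODES.get(_get(demo_row, "sex").upper(), "unknown")
    reporter = REPORTER_CODES.get(_get(demo_row, "occp_cod").upper(), "unknown")
    country = _get(demo_row, "reporter_country") or None

    fda_date, _ = parse_faers_date(_get(demo_row, "fda_dt"), log)
    event_date, event_partial = parse_faers_date(_get(demo_row, "event_dt"), log)

    start_date: _dt.date | None = None
    start_partial = False
    for row in ther_rows:
        d, partial = parse_faers_date(_get(row, "start_dt"), log)
        if d is not None and (start_date is None or d < start_date):
            start_date, start_partial = d, partial

    outcomes = set()
    for row in outc_rows:
        code = _get(row, "outc_cod").upper()
        if not code:
            continue
        mapped = OUTCOME_CODES.get(code)
        if mapped is None:
            log.warnings["unknown_outc_cod"] += 1
        else:
            outcomes.add(mapped)

    drugs = []
    for row in drug_rows:
        name = _get(row, "drugname")
        role = _get(row, "role_cod").upper()
        if name:
            drugs.append((name, role if role in ("PS", "SS", "C", "I") else "C"))

    events = {pt for row in reac_rows if (pt := _get(row, "pt"))}

    return ReportCase(
        primaryid=pid,
        caseid=caseid,
        fda_date=fda_date,
        sex=sex,
        age_years=age,
        weight_kg=wt,
        country=country,
        reporter=reporter,
        outcomes=frozenset(outcomes),
        drugs=tuple(drugs),
        events=frozenset(events),
        event_date=event_date,
        therapy_start=start_date,
        event_date_partial=event_partial,
        therapy_start_partial=start_partial,
    )


def normalize_cases(raw: RawTables, log: IngestLog | None = None) -> list[ReportCase]:
    """Normalize every DEMO row of (deduplicated) RawTables."""
    log = log if log is not None else raw.log
    children = {}
    for name in ("drug", "reac", "outc", "ther"):
        t = raw.table(name)
        children[name] = (
            {pid: grp.to_dict("records") for pid, grp in t.groupby("primaryid")}
            if len(t)
            else {}
        )
    cases = []
    for demo_row in raw.demo.to_dict("records"):
        pid = str(demo_row.get("primaryid", "")).strip()
        cases.append(
            normalize_case(
                demo_row,
                children["drug"].get(pid, ()),
                children["reac"].get(pid, ()),
                children["outc"].get(pid, ()),
                children["ther"].get(pid, ()),
                log=log,
            )
        )
    return cases


def select_target_reports(
    cases: Sequence[ReportCase],
    names: Iterable[str],
    roles: Iterable[str] = ("PS",),
) -> tuple[list[ReportCase], list[ReportCase]]:
    """Partition cases into (exposed, unexposed) by drug-name match.

    A case is exposed when at least one of its drug entries matches any
    target name (case-insensitive substring after trimming) *and* carries
    a role in ``roles`` (default: primary suspect only).
    """
    needles = [n.strip().lower() for n in names if n and n.strip()]
    if not needles:
        raise ValueError("at least one target drug name is required")
    role_set = set(roles)
    exposed, unexposed = [], []
    for case in cases:
        hit = any(
            role in role_set and any(n in name.strip().lower() for n in needles)
            for name, role in case.drugs
        )
        (exposed if hit else unexposed).append(case)
    return exposed, unexposed


@dataclass(frozen=True)
class PTAnnotation:
    pt: str
    soc: str
    dme: bool
    ime: bool
    evidence: str | None  # "++", "+", "-" or None


@dataclass
class Annotation:
    """User-supplied PT->SOC map plus EMA DME/IME lists and evidence grades."""

    pt_to_soc: dict[str, str]
    dme_terms: set[str] = field(default_factory=set)
    ime_terms: set[str] = field(default_factory=set)
    evidence: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def _norm(pt: str) -> str:
        return pt.strip().lower()

    @classmethod
    def from_tsvs(
        cls,
        pt_to_soc: str | Path,
        dme: str | Path | None = None,
        ime: str | Path | None = None,
        evidence: str | Path | None = None,
    ) -> "Annotation":
        soc_df = pd.read_csv(pt_to_soc, sep="\t", dtype=str)
        mapping = {
            cls._norm(r["pt"]): str(r["soc"]).strip()
            for r in soc_df.to_dict("records")
        }
        def read_terms(path):
            if path is None:
                return set()
            df = pd.read_csv(path, sep="\t", dtype=str)
            return {cls._norm(p) for p in df["pt"]}
        ev = {}
        if evidence is not None:
            df = pd.read_csv(evidence, sep="\t", dtype=str)
            ev = {cls._norm(r["pt"]): str(r["grade"]).strip() for r in df.to_dict("records")}
        return cls(mapping, read_terms(dme), read_terms(ime), ev)

    def lookup(self, pt: str) -> PTAnnotation:
        key = self._norm(pt)
        soc = self.pt_to_soc.get(key)
        if soc is None:
            logger.debug("PT %r has no SOC mapping", pt)
            soc = "UNMAPPED"
        return PTAnnotation(
            pt=pt,
            soc=soc,
            dme=key in self.dme_terms,
            ime=key in self.ime_terms,
            evidence=self.evidence.get(key),
        )

    def soc_members(self, soc: str) -> set[str]:
        return {pt for pt, s in self.pt_to_soc.items() if s == soc}


def annotate(events: Iterable[str], annotation: Annotation) -> dict[str, PTAnnotation]:
    """Annotate each PT with its SOC, DME/IME membership and evidence grade."""
    return {pt: annotation.lookup(pt) for pt in events}
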