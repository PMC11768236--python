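"""Parsing, deduplication, unit normalization and target-drug selection."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from faersignal import synthetic
from faersignal.ingest import (
    IngestLog,
    annotate,
    deduplicate,
    normalize_case,
    normalize_cases,
    read_quarter,
    select_target_reports,
)

from conftest import write_quarter_files, TINY_QUARTER


class TestReadQuarter:
    def test_row_counts_match_fixture(self, tiny_quarter):
        raw = read_quarter(tiny_quarter)
        assert raw.row_counts() == {"demo": 5, "drug": 7, "reac": 6, "outc": 3, "ther": 2}

    def test_malformed_row_is_skipped_and_counted(self, tmp_path):
        tables = dict(TINY_QUARTER)
        tables["demo"] = tables["demo"] + ["999$99$20220101$extra$field$too$many$x$y$z$w$EXTRA"]
        write_quarter_files(tmp_path / "q", tables)
        raw = read_quarter(tmp_path / "q")
        assert len(raw.demo) == 5
        assert raw.log.rows_skipped["demo"] == 1

    def test_missing_mandatory_table_raises(self, tmp_path):
        tables = {k: v for k, v in TINY_QUARTER.items() if k != "reac"}
        write_quarter_files(tmp_path / "q", tables)
        with pytest.raises(FileNotFoundError, match="REAC"):
            read_quarter(tmp_path / "q")

    def test_missing_optional_table_yields_empty(self, tmp_path):
        tables = {k: v for k, v in TINY_QUARTER.items() if k not in ("outc", "ther")}
        write_quarter_files(tmp_path / "q", tables)
        raw = read_quarter(tmp_path / "q")
        assert len(raw.outc) == 0 and len(raw.ther) == 0

    def test_generator_parser_round_trip(self, tmp_path):
        config = synthetic.SyntheticConfig(n_reports=1000, seed=42)
        cases, truth = synthetic.simulate(config)
        synthetic.write_quarter(truth, tmp_path / "q")
        raw = read_quarter(tmp_path / "q")
        assert len(raw.demo) == truth.n_demo_rows
        parsed = normalize_cases(deduplicate(raw))
        assert len(parsed) == truth.n_unique_cases == 1000
        by_case = {c.caseid: c for c in cases}
        for c in parsed:
            ref = by_case[c.caseid]
            assert (c.primaryid, c.sex, c.reporter, c.country) == (
                ref.primaryid, ref.sex, ref.reporter, ref.country
            )
            assert c.events == ref.events and c.outcomes == ref.outcomes
            assert c.event_date == ref.event_date
            assert c.therapy_start == ref.therapy_start
            for got, want in ((c.age_years, ref.age_years), (c.weight_kg, ref.weight_kg)):
                assert (got is None) == (want is None)
                if got is not None:
                    assert got == pytest.approx(want)


class TestDeduplicate:
    def _raw(self, tmp_path, demo_extra):
        tables = dict(TINY_QUARTER)
        tables["demo"] = tables["demo"] + demo_extra
        write_quarter_files(tmp_path / "q", tables)
        return read_quarter(tmp_path / "q")

    def test_latest_fda_date_version_is_kept(self, tmp_path):
        raw = self._raw(tmp_path, [
            "771$77$20200101$$30$YR$F$$$US$MD",
            "772$77$20210101$$30$YR$F$$$US$MD",
        ])
        deduped = deduplicate(raw)
        kept = set(deduped.demo["primaryid"])
        assert "772" in kept and "771" not in kept

    def test_tie_broken_by_largest_primaryid(self, tmp_path):
        raw = self._raw(tmp_path, [
            "775$77$20200101$$30$YR$F$$$US$MD",
            "773$77$20200101$$30$YR$F$$$US$MD",
        ])
        deduped = deduplicate(raw)
        assert "775" in set(deduped.demo["primaryid"])

    def test_identity_on_distinct_cases_and_idempotence(self, tiny_quarter):
        raw = read_quarter(tiny_quarter)
        once = deduplicate(raw)
        assert list(once.demo["primaryid"]) == list(raw.demo["primaryid"])
        twice = deduplicate(once)
        assert twice.demo.equals(once.demo)
        assert twice.drug.equals(once.drug)

    def test_generator_duplicates_recovered(self, tmp_path):
        config = synthetic.SyntheticConfig(n_reports=800, duplicate_rate=0.1, seed=7)
        _, truth = synthetic.generate(config, tmp_path / "q")
        raw = read_quarter(tmp_path / "q")
        assert len(raw.demo) == truth.n_demo_rows > 800
        deduped = deduplicate(raw)
        assert len(deduped.demo) == truth.n_unique_cases == 800


class TestNormalizeCase:
    @pytest.mark.parametrize(
        "age, cod, expected",
        [("24", "MON", 2.0), ("3", "DEC", 30.0), ("36", "YR", 36.0),
         ("730.5", "DY", 2.0), ("", "", None), ("abc", "YR", None)],
    )
    def test_age_unit_conversion(self, age, cod, expected):
        case = normalize_case({"primaryid": "1", "caseid": "1", "age": age, "age_cod": cod})
        if expected is None:
            assert case.age_years is None
        else:
            assert case.age_years == pytest.approx(expected)

    def test_weight_lbs_to_kg(self):
        case = normalize_case({"primaryid": "1", "caseid": "1", "wt": "154", "wt_cod": "LBS"})
        assert case.weight_kg == pytest.approx(154 * 0.45359237)

    def test_outcome_codes_and_serious_flag(self):
        case = normalize_case(
            {"primaryid": "1", "caseid": "1"},
            outc_rows=[{"outc_cod": "DE"}, {"outc_cod": "CA"}, {"outc_cod": "RI"}],
        )
        assert case.outcomes == frozenset({"death", "other_serious"})
        assert case.serious
        assert not normalize_case({"primaryid": "1", "caseid": "1"}).serious

    def test_partial_dates_resolved_and_flagged(self):
        case = normalize_case(
            {"primaryid": "1", "caseid": "1", "event_dt": "202003"},
            ther_rows=[{"start_dt": "2020"}],
        )
        assert case.event_date == dt.date(2020, 3, 1) and case.event_date_partial
        assert case.therapy_start == dt.date(2020, 1, 1) and case.therapy_start_partial

    @settings(max_examples=200, deadline=None)
    @given(
        row=st.dictionaries(
            st.sampled_from(["primaryid", "caseid", "age", "age_cod", "wt", "wt_cod",
                             "sex", "occp_cod", "fda_dt", "event_dt", "reporter_country"]),
            st.text(max_size=12),
        )
    )
    def test_never_raises_on_arbitrary_text(self, row):
        row.setdefault("primaryid", "1")
        case = normalize_case(row, log=IngestLog())
        assert case.age_years is None or case.age_years >= 0
        assert case.weight_kg is None or case.weight_kg >= 0


class TestSelectTargetReports:
    def test_rules(self, tiny_quarter):
        cases = normalize_cases(read_quarter(tiny_quarter))
        exposed, unexposed = select_target_reports(cases, {"canakinumab", "ilaris"})
        ids = {c.primaryid for c in exposed}
        # 101: ILARIS/PS -> exposed. 301: canakinumab/C -> role filter excludes.
        # 401: substring "Canakinumab injection"/PS -> exposed. 501: ILARIS/SS -> excluded.
        assert ids == {"101", "401"}
        assert len(exposed) + len(unexposed) == len(cases)

    def test_empty_names_error(self, tiny_quarter):
        cases = normalize_cases(read_quarter(tiny_quarter))
        with pytest.raises(ValueError):
            select_target_reports(cases, set())

    def test_generator_truth_exposed_count(self):
        cases, truth = synthetic.simulate(synthetic.SyntheticConfig(n_reports=2000, seed=3))
        exposed, unexposed = select_target_reports(cases, {"canakinumab", "ilaris"})
        assert len(exposed) == truth.exposed_count()
        assert len(exposed) + len(unexposed) == 2000


class TestAnnotate:
    def test_lookup_and_unmapped(self, annotation):
        out = annotate(["Deafness", "Novel term"], annotation)
        assert out["Deafness"].soc == "Ear and labyrinth disorders"
        assert out["Deafness"].dme and out["Deafness"].ime
        assert out["Novel term"].soc == "UNMAPPED"

    def test_dme_and_ime_reported_independently(self, annotation):
        out = annotation.lookup("Pneumonia")
        assert out.ime and not out.dme and out.evidence == "++"
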