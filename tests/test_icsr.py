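"""Report model, CSV round-trips and deduplication."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nwsignal.icsr import (
    ConsistencyError,
    DrugEntry,
    IcsrReport,
    PatientInfo,
    ReactionEntry,
    ReportSet,
    SchemaError,
    deduplicate,
    read_reports,
    write_reports,
)

from conftest import make_report


class TestModelValidation:
    def test_drug_name_normalized(self):
        d = DrugEntry(name="  Paroxetine ", atc_code="n06ab05")
        assert d.name == "paroxetine"
        assert d.atc_code == "N06AB05"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"name": "x", "role": "prescribed"},
            {"name": "x", "daily_dose_ddd": -1.0},
            {"name": ""},
        ],
    )
    def test_invalid_drug_entry_raises(self, kwargs):
        with pytest.raises(SchemaError):
            DrugEntry(**kwargs)

    def test_report_requires_drugs_and_reactions(self):
        with pytest.raises(SchemaError):
            IcsrReport(
                report_id="R1",
                patient=PatientInfo(),
                drugs=[],
                reactions=[ReactionEntry(pt="rash")],
            )
        with pytest.raises(SchemaError):
            IcsrReport(
                report_id="R1",
                patient=PatientInfo(),
                drugs=[DrugEntry(name="x")],
                reactions=[],
            )

    def test_reportset_rejects_duplicate_ids(self):
        with pytest.raises(ConsistencyError):
            ReportSet(reports=[make_report("R1"), make_report("R1", drug="other")])


class TestReadWrite:
    def test_long_rows_merge_into_one_report(self, tmp_path):
        """Three long rows sharing a report_id (1 drug x 3 reactions) merge
        into one report with three reactions."""
        path = tmp_path / "long.csv"
        rep = make_report("R1", extra_pts=["tremor", "irritability"])
        write_reports(ReportSet(reports=[rep]), str(path), "long")
        assert sum(1 for _ in open(path)) == 4  # header + 1 drug x 3 reactions
        rs = read_reports(str(path), "long")
        assert len(rs) == 1
        assert len(rs.reports[0].reactions) == 3

    def test_relational_missing_age_stays_absent(self, tmp_path):
        reps = [make_report("R1"), make_report("R2", age_days=None, drug="sertraline")]
        d = tmp_path / "rel"
        write_reports(ReportSet(reports=reps), str(d), "relational")
        rs = read_reports(str(d), "relational")
        assert len(rs) == 2
        assert rs.reports[1].patient.age_days is None

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_reports(ReportSet(), str(path), "long")
        lines = open(path).read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("report_id")
        assert len(read_reports(str(path), "long")) == 0

    def test_cartesian_long_rows(self, tmp_path):
        rep = make_report(
            "R1", extra_drugs=[DrugEntry(name="diazepam", role="concomitant")],
            extra_pts=["tremor"],
        )
        path = tmp_path / "cart.csv"
        write_reports(ReportSet(reports=[rep]), str(path), "long")
        assert sum(1 for _ in open(path)) == 5  # header + 2 drugs x 2 reactions

    @pytest.mark.parametrize("dialect", ["long", "relational"])
    def test_round_trip_identity(self, tmp_path, dialect, small_sim):
        """write(read(write(x))) recovers an equal ReportSet field by field
        on a generated database slice."""
        _, rs, _ = small_sim
        subset = ReportSet(reports=rs.reports[:200])
        p1 = tmp_path / "a"
        write_reports(subset, str(p1), dialect)
        back = read_reports(str(p1), dialect)
        assert back == subset

    def test_missing_column_names_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("report_id,age_days\nR1,5\n")
        with pytest.raises(SchemaError, match="sex"):
            read_reports(str(path), "long")

    def test_conflicting_report_fields_raise(self, tmp_path):
        rep = make_report("R1")
        path = tmp_path / "conflict.csv"
        write_reports(ReportSet(reports=[rep]), str(path), "long")
        lines = open(path).read().splitlines()
        # clone the row but flip the sex field
        lines.append(lines[1].replace("female", "male"))
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ConsistencyError, match="R1"):
            read_reports(str(path), "long")


class TestDeduplicate:
    def test_exact_clone_collapses(self):
        a = make_report("R1")
        b = dataclasses.replace(a, report_id="R2")
        out = deduplicate(ReportSet(reports=[a, b]))
        assert [r.report_id for r in out] == ["R1"]

    @pytest.mark.parametrize(
        "change",
        [
            {"age_days": 6},
            {"sex": "male"},
            {"country": "SE"},
            {"drug": "sertraline"},
            {"pt": "withdrawal syndrome"},
        ],
    )
    def test_any_key_field_difference_retains_both(self, change):
        a = make_report("R1")
        b = make_report("R2", **change)
        assert len(deduplicate(ReportSet(reports=[a, b]))) == 2

    def test_planted_clones_recover_distinct_reports(self):
        """k clones each of m distinct reports -> exactly m survivors;
        oracle = grouping by the dedup key."""
        m, k = 7, 4
        distinct = [make_report(f"R{i}", age_days=i + 1) for i in range(m)]
        clones = [
            dataclasses.replace(r, report_id=f"C{i}-{j}")
            for i, r in enumerate(distinct)
            for j in range(k)
        ]
        rs = ReportSet(reports=distinct + clones)
        assert len({r.dedup_key() for r in rs}) == m  # oracle
        out = deduplicate(rs)
        assert len(out) == m
        assert out.reports == distinct  # first occurrences, unchanged

    def test_idempotent(self, small_sim):
        _, rs, _ = small_sim
        once = deduplicate(rs)
        assert deduplicate(once) == once


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["paroxetine", "sertraline", "clomipramine"]),
            st.integers(min_value=1, max_value=27),
            st.sampled_from(["female", "male", "unknown"]),
        ),
        min_size=0,
        max_size=8,
    )
)
def test_random_sets_round_trip_long(tmp_path_factory, entries):
    """Round-trip identity holds on randomized valid report sets."""
    reports = [
        make_report(f"R{i}", drug=d, age_days=a, sex=s)
        for i, (d, a, s) in enumerate(entries)
    ]
    rs = ReportSet(reports=reports)
    path = tmp_path_factory.mktemp("rt") / "x.csv"
    write_reports(rs, str(path), "long")
    assert read_reports(str(path), "long") == rs
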