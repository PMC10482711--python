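"""Contingency construction, ROR/IC arithmetic, signal rule and the
analysis suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from nwsignal.casedef import build_analysis_set
from nwsignal.disprop import (
    ContingencyTable,
    DisproportionalityResult,
    IcEstimate,
    contingency_table,
    expected_count,
    information_component,
    results_to_frame,
    ror,
    run_analysis_suite,
)
from nwsignal.icsr import DrugEntry, ReportSet

from conftest import make_report

cells = st.integers(min_value=0, max_value=500)


def _aset_from_counts(n_case_drug, n_case_bg, n_noncase_drug, n_noncase_bg, drug="sertraline"):
    reports = []
    i = 0

    def add(n, case, exposed):
        nonlocal i
        for _ in range(n):
            reports.append(
                make_report(
                    f"R{i}",
                    drug=drug if exposed else "paracetamol",
                    pt="drug withdrawal syndrome neonatal" if case else "rash",
                    age_days=(i % 27) + 1,
                )
            )
            i += 1

    add(n_case_drug, True, True)
    add(n_case_bg, True, False)
    add(n_noncase_drug, False, True)
    add(n_noncase_bg, False, False)
    return build_analysis_set(ReportSet(reports=reports))


class TestContingency:
    def test_enumeration_example(self):
        """2 cases + 3 non-cases on the drug vs 1 case + 4 non-cases on
        background -> (2,3,1,4)."""
        aset = _aset_from_counts(2, 1, 3, 4)
        t = contingency_table(aset, "sertraline", "main")
        assert t.cells() == (2, 3, 1, 4)

    def test_empty_exposed_arm(self):
        aset = _aset_from_counts(0, 2, 0, 5)
        t = contingency_table(aset, "sertraline", "main")
        assert t.cells() == (0, 0, 2, 5)

    def test_positive_control_scheme(self):
        reports = [
            make_report("R1", drug="sertraline"),
            make_report("R2", drug="methadone"),
            make_report("R3", drug="methadone", pt="rash"),
            make_report("R4", drug="paracetamol", pt="rash"),
        ]
        aset = build_analysis_set(ReportSet(reports=reports))
        t = contingency_table(aset, "sertraline", "positive_control")
        assert t.cells() == (1, 0, 1, 1)

    def test_intraclass_scheme_and_tie_to_exposed(self):
        reports = [
            make_report("R1", drug="paroxetine"),
            # both paroxetine and sertraline: exposed arm wins the tie
            make_report("R2", drug="paroxetine",
                        extra_drugs=[DrugEntry(name="sertraline", role="suspected")]),
            make_report("R3", drug="sertraline", pt="rash"),
            make_report("R4", drug="fluoxetine"),
        ]
        aset = build_analysis_set(ReportSet(reports=reports))
        t = contingency_table(aset, "paroxetine", "intraclass")
        assert t.cells() == (2, 0, 1, 1)

    def test_counts_match_truth_within_3se(self, small_sim, small_aset):
        """Generated databases hit the closed-form expected cells to within
        three binomial standard errors."""
        cfg, _, truth = small_sim
        frame = truth.frame.set_index("drug")
        for drug in ("paroxetine", "clomipramine", "venlafaxine"):
            t = contingency_table(small_aset, drug, "main")
            row = frame.loc[drug]
            for cell, exp in [
                (t.a, row["expected_a"]),
                (t.b, row["expected_b"]),
                (t.c, row["expected_c"]),
                (t.d, row["expected_d"]),
            ]:
                se = math.sqrt(max(exp, 1.0))
                assert abs(cell - exp) < 4 * se  # 3 SE + dedup/rounding slack

    def test_intraclass_needs_other_class_members(self, small_aset):
        with pytest.raises(ValueError):
            contingency_table(small_aset, "antidepressants", "intraclass")


class TestRor:
    def test_symmetric_table(self):
        est = ror(ContingencyTable(10, 10, 10, 10))
        assert est.estimate == pytest.approx(1.0)
        assert est.lo < 1.0 < est.hi

    def test_woolf_example(self):
        """(20,80,100,9900): ROR 24.75, CI from ln ROR +/- 1.96 * 0.26945."""
        est = ror(ContingencyTable(20, 80, 100, 9900))
        assert est.estimate == pytest.approx(24.75)
        assert est.lo == pytest.approx(14.60, abs=0.01)
        assert est.hi == pytest.approx(41.96, abs=0.01)

    def test_zero_cell_undefined_without_correction(self):
        est = ror(ContingencyTable(0, 10, 10, 100))
        assert not est.defined
        assert "zero cell" in est.reason

    def test_haldane_correction(self):
        est = ror(ContingencyTable(0, 10, 10, 100), correction="haldane")
        assert est.estimate == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))

    def test_haldane_no_op_without_zero(self):
        t = ContingencyTable(5, 6, 7, 8)
        assert ror(t, "haldane") == ror(t, "none")

    def test_all_zero_undefined(self):
        assert not ror(ContingencyTable(0, 0, 0, 0), "haldane").defined

    @settings(max_examples=100, deadline=None)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_swap_reciprocal_invariance(self, a, b, c, d):
        fwd = ror(ContingencyTable(a, b, c, d), "haldane")
        rev = ror(ContingencyTable(c, d, a, b), "haldane")
        if fwd.defined:
            assert fwd.estimate * rev.estimate == pytest.approx(1.0)
            assert fwd.lo * rev.hi == pytest.approx(1.0)

    def test_against_statsmodels_oracle(self):
        """Independent route: statsmodels' 2x2 OR and Woolf CI."""
        from statsmodels.stats.contingency_tables import Table2x2

        for cells_ in [(20, 80, 100, 9900), (12, 7, 33, 41), (3, 50, 8, 212)]:
            a, b, c, d = cells_
            sm = Table2x2(np.array([[a, b], [c, d]]))
            est = ror(ContingencyTable(a, b, c, d))
            assert est.estimate == pytest.approx(sm.oddsratio)
            lo, hi = sm.oddsratio_confint(0.05)
            assert est.lo == pytest.approx(lo)
            assert est.hi == pytest.approx(hi)


class TestInformationComponent:
    @pytest.mark.parametrize(
        "a, e, expected",
        [
            (10, 10.0, 0.0),
            (8, 2.0, math.log2(8.5 / 2.5)),
            (0, 0.5, -1.0),
        ],
    )
    def test_point_estimates(self, a, e, expected):
        assert information_component(a, e).ic == pytest.approx(expected)

    def test_bounds_bracket_estimate(self):
        est = information_component(12, 3.0)
        assert est.lo < est.ic < est.hi

    def test_invalid_expected_raises(self):
        with pytest.raises(ValueError):
            information_component(5, 0.0)

    def test_monotone_in_observed(self):
        ics = [information_component(a, 10.0).ic for a in range(0, 60, 3)]
        assert all(x < y for x, y in zip(ics, ics[1:]))

    @pytest.mark.parametrize("a", [1, 5, 20, 100])
    @pytest.mark.parametrize("e", [1.0, 2.0, 10.0, 50.0])
    def test_shrinkage_toward_null(self, a, e):
        assert abs(information_component(a, e).ic) <= abs(math.log2(a / e)) + 1e-12

    def test_wald_alternative_close_to_gamma_for_large_counts(self):
        g = information_component(200, 100.0, "gamma")
        w = information_component(200, 100.0, "wald")
        assert g.lo == pytest.approx(w.lo, abs=0.02)
        assert g.hi == pytest.approx(w.hi, abs=0.02)

    def test_expected_count_frame(self):
        t = ContingencyTable(2, 3, 1, 4)
        assert expected_count(t) == pytest.approx((5 * 3) / 10)


class TestSignalRule:
    @settings(max_examples=150, deadline=None)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_signal_equivalence(self, a, b, c, d):
        """signal <=> (ror_lo > 1) and (ic_lo > 0), exhaustively over
        randomized tables."""
        t = ContingencyTable(a, b, c, d)
        e = expected_count(t)
        ic = information_component(a, e) if e > 0 else IcEstimate(0.0, 0.0, 0.0)
        r = DisproportionalityResult(table=t, ror=ror(t, "haldane"), ic=ic, analysis_tag="drug")
        expected = r.ror.defined and r.ror.lo > 1 and r.ic.lo > 0
        assert r.signal == expected


@pytest.fixture(scope="module")
def results(small_aset):
    return run_analysis_suite(small_aset, min_cases=4)


class TestSuite:
    def test_pooled_and_class_rows_present(self, results):
        tags = {(r.table.exposure_label, r.analysis_tag) for r in results}
        assert ("antidepressants", "main") in tags
        assert ("tca", "class") in tags and ("ssri", "class") in tags

    def test_min_cases_threshold(self, small_aset, results):
        """Drugs below the case threshold are excluded from drug-level
        output but their class row remains."""
        drug_rows = {r.table.exposure_label for r in results if r.analysis_tag == "drug"}
        for r in results:
            if r.analysis_tag == "drug":
                assert r.table.a >= 4
        for drug in small_aset.class_map.all_drugs():
            t = contingency_table(small_aset, drug, "main")
            assert (drug in drug_rows) == (t.a >= 4)

    def test_drug_rows_have_all_three_schemes(self, results):
        drugs = {r.table.exposure_label for r in results if r.analysis_tag == "drug"}
        intraclass = {r.table.exposure_label for r in results if r.analysis_tag == "intraclass"}
        pc = {r.table.exposure_label for r in results if r.analysis_tag == "positive_control"}
        assert drugs <= intraclass
        assert drugs <= pc

    def test_frame_round_trip(self, results):
        df = results_to_frame(results)
        assert len(df) == len(results)
        assert set(df.columns) >= {"exposure", "ror", "ror_lo", "ic", "ic_lo", "signal"}
        assert df["signal"].dtype == bool
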