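"""Triage rules, contingency tables, diagnostic metrics and NNT."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triagecea import (
    Cohort,
    ContingencyTable,
    PatientRecord,
    TriageStrategy,
    builtin_strategies,
    contingency,
    diagnostic_metrics,
    get_strategy,
    is_cspca,
    nnt,
)


def rec(psad=0.1, pirads=1, primary=1, isup=0, pid="p"):
    return PatientRecord(pid, psad=psad, pirads=pirads, primary_score=primary, isup=isup)


class TestBuiltinRules:
    def test_six_builtins_in_canonical_order(self):
        assert [s.name for s in builtin_strategies()] == [
            "biopsy_all", "psad", "mpmri", "pet", "mpmri_or_pet", "psad_and_mpmri",
        ]

    def test_psad_threshold_is_strict(self):
        s = get_strategy("psad")
        assert not s.refers(rec(psad=0.15))
        assert s.refers(rec(psad=0.151))

    def test_or_rule_referred_on_pet_alone(self):
        assert get_strategy("mpmri_or_pet").refers(rec(pirads=2, primary=4))

    def test_and_rule_needs_both(self):
        s = get_strategy("psad_and_mpmri")
        assert not s.refers(rec(psad=0.2, pirads=2))
        assert not s.refers(rec(psad=0.1, pirads=4))
        assert s.refers(rec(psad=0.2, pirads=4))

    def test_missing_score_is_not_referred_and_warned(self, caplog):
        r = PatientRecord("m", psad=0.2, pirads=None, primary_score=None, isup=2)
        with caplog.at_level(logging.WARNING, logger="triagecea.strategies"):
            assert not get_strategy("mpmri").refers(r)
            assert not get_strategy("mpmri_or_pet").refers(r)
        assert "treated as negative" in caplog.text

    def test_unknown_strategy_name(self):
        with pytest.raises(KeyError, match="unknown strategy"):
            get_strategy("nope")


class TestContingency:
    def test_fixture_mpmri_cells(self, cohort130, strategies):
        t = contingency(cohort130, strategies["mpmri"])
        assert (t.tp, t.fp, t.fn, t.tn) == (17, 17, 9, 87)

    def test_fixture_biopsy_all(self, cohort130, strategies):
        t = contingency(cohort130, strategies["biopsy_all"])
        assert (t.tp, t.fp, t.fn, t.tn) == (26, 104, 0, 0)

    def test_never_refer_is_complement_of_biopsy_all(self, cohort130):
        never = TriageStrategy("never", "Never", lambda r: False, frozenset({"psa"}))
        t = contingency(cohort130, never)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 26, 104)

    def test_empty_cohort_rejected(self, strategies):
        with pytest.raises(ValueError, match="empty"):
            contingency(Cohort(()), strategies["mpmri"])


class TestDiagnosticMetrics:
    def test_fixture_mpmri_metrics(self):
        m = diagnostic_metrics(ContingencyTable(17, 17, 9, 87))
        assert m.sensitivity == pytest.approx(17 / 26, abs=5e-4)  # ~0.654
        assert m.specificity == pytest.approx(87 / 104, abs=5e-4)  # ~0.837
        assert m.accuracy == pytest.approx(104 / 130)

    def test_biopsy_all_has_undefined_npv(self):
        m = diagnostic_metrics(ContingencyTable(26, 104, 0, 0))
        assert m.sensitivity == 1.0
        assert m.npv is None and m.specificity == 0.0

    def test_perfect_test(self):
        m = diagnostic_metrics(ContingencyTable(26, 0, 0, 104))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)

    def test_all_zero_table_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            diagnostic_metrics(ContingencyTable(0, 0, 0, 0))


class TestNnt:
    @pytest.mark.parametrize(
        "biopsies,detected,display",
        [(130, 26, "5.0"), (61, 17, "3.6"), (25, 18, "1.4"), (42, 22, "1.9"), (20, 12, "1.7")],
    )
    def test_one_decimal_display(self, biopsies, detected, display):
        assert f"{nnt(biopsies, detected):.1f}" == display

    def test_zero_detected_is_undefined_marker(self):
        assert nnt(10, 0) is None

    def test_detected_cannot_exceed_biopsies(self):
        with pytest.raises(ValueError):
            nnt(5, 6)


# --- property tests against a per-record brute-force oracle ----------------

record_strategy = st.builds(
    PatientRecord,
    patient_id=st.uuids().map(str),
    psad=st.floats(0, 1, allow_nan=False),
    pirads=st.one_of(st.none(), st.integers(1, 5)),
    primary_score=st.one_of(st.none(), st.integers(1, 5)),
    isup=st.integers(0, 5),
)
small_cohorts = st.lists(record_strategy, min_size=1, max_size=10, unique_by=lambda r: r.patient_id).map(
    Cohort.from_records
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(small_cohorts)
def test_contingency_matches_per_record_counting(cohort):
    """Exhaustive per-record predicate counting is the oracle for contingency()."""
    for s in builtin_strategies():
        t = contingency(cohort, s)
        expect = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for r in cohort:
            if s.refers(r) and is_cspca(r):
                expect["tp"] += 1
            elif s.refers(r):
                expect["fp"] += 1
            elif is_cspca(r):
                expect["fn"] += 1
            else:
                expect["tn"] += 1
        assert (t.tp, t.fp, t.fn, t.tn) == tuple(expect.values())
        assert t.n == cohort.n


@settings(max_examples=60, deadline=None, derandomize=True)
@given(small_cohorts)
def test_combination_strategy_monotonicity(cohort):
    """OR detects at least each component; AND biopsies at most each component."""
    det = {}
    biop = {}
    for s in builtin_strategies():
        t = contingency(cohort, s)
        det[s.name], biop[s.name] = t.tp, t.referred
        assert t.tp + t.fn == cohort.n_cspca  # strategy-independent
    assert det["mpmri_or_pet"] >= max(det["mpmri"], det["pet"])
    assert biop["psad_and_mpmri"] <= min(biop["psad"], biop["mpmri"])
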