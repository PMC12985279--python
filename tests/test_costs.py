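"""Cost allocation: utilization counts, exact totals, paradigm ordering."""

import pytest

from triagecea import (
    AllocationParadigm,
    TestUtilization,
    TriageStrategy,
    UnitCostTable,
    cost_per_detection,
    per_patient_cost_cents,
    round_eur,
    total_cost,
    total_cost_cents,
    utilization,
)
from triagecea.synthetic import PerformanceSpec, simulate_cohort


class TestUtilizationCounts:
    def test_or_strategy_stepwise(self, cohort130, strategies):
        """PET billed only for mpMRI-negative, PET-positive patients (42-34=8)."""
        u = utilization(cohort130, strategies["mpmri_or_pet"], "stepwise")
        assert u.as_dict() == {"psa": 130, "mpmri": 130, "pet": 8, "biopsy": 42, "pathology": 42}

    def test_and_strategy_stepwise(self, cohort130, strategies):
        """mpMRI only in the 61 patients with elevated PSA density."""
        u = utilization(cohort130, strategies["psad_and_mpmri"], "stepwise")
        assert u.as_dict() == {"psa": 130, "mpmri": 61, "pet": 0, "biopsy": 20, "pathology": 20}

    def test_pet_universal_scans_everyone(self, cohort130, strategies):
        u = utilization(cohort130, strategies["pet"], AllocationParadigm.UNIVERSAL)
        assert u.n_pet == 130 and u.n_mpmri == 0

    def test_unknown_paradigm(self, cohort130, strategies):
        with pytest.raises(ValueError, match="unknown paradigm"):
            utilization(cohort130, strategies["pet"], "middleout")

    def test_custom_strategy_needs_stepwise_plan(self, cohort130):
        custom = TriageStrategy("c", "C", lambda r: True, frozenset({"psa", "pet"}))
        with pytest.raises(ValueError, match="stepwise plan"):
            utilization(cohort130, custom, "stepwise")
        assert utilization(cohort130, custom, "universal").n_pet == 130

    def test_biopsy_always_implies_pathology(self):
        with pytest.raises(ValueError, match="pathology"):
            TestUtilization(1, 0, 0, 3, 2)


class TestTotals:
    def test_biopsy_all_total(self, unit_costs):
        u = TestUtilization(130, 0, 0, 130, 130)
        assert round_eur(total_cost(u, unit_costs)) == 116058

    def test_or_strategy_total(self, unit_costs):
        u = TestUtilization(130, 130, 8, 42, 42)
        assert total_cost(u, unit_costs) == pytest.approx(81990.9)
        assert round_eur(total_cost(u, unit_costs)) == 81991

    def test_all_zero_utilization(self, unit_costs):
        assert total_cost(TestUtilization(0, 0, 0, 0, 0), unit_costs) == 0

    def test_linearity_in_unit_costs(self, unit_costs):
        u = TestUtilization(130, 130, 8, 42, 42)
        doubled = UnitCostTable(**{k: 2 * v for k, v in unit_costs.to_dict().items()})
        assert total_cost_cents(u, doubled) == 2 * total_cost_cents(u, unit_costs)

    @pytest.mark.parametrize(
        "total,detected,expected",
        [(116058, 26, 4464), (144422, 18, 8023), (67357, 17, 3962), (35319, 12, 2943)],
    )
    def test_cost_per_detection(self, total, detected, expected):
        assert round_eur(cost_per_detection(total, detected)) == expected

    def test_cost_per_detection_undefined_at_zero(self):
        assert cost_per_detection(1000, 0) is None

    def test_round_eur_half_away_from_zero(self):
        assert round_eur(116057.5) == 116058
        assert round_eur(-28.47) == -28
        assert round_eur(-522.78) == -523


class TestPerPatientLedgerOracle:
    """Summing each patient's individually incurred procedures must equal
    the utilization-based total, for both paradigms on random cohorts."""

    @pytest.mark.parametrize("seed", [11, 12, 13])
    @pytest.mark.parametrize("paradigm", ["stepwise", "universal"])
    def test_ledger_equals_utilization_total(self, unit_costs, strategies, seed, paradigm):
        cohort = simulate_cohort(25, PerformanceSpec(), seed=seed)
        for s in strategies.values():
            ledger = sum(per_patient_cost_cents(cohort, s, unit_costs, paradigm))
            util_total = total_cost_cents(utilization(cohort, s, paradigm), unit_costs)
            assert ledger == util_total


def test_universal_never_cheaper_than_stepwise(cohort130, strategies, unit_costs):
    """Universal allocation performs a superset of tests, so costs dominate;
    strictly for strategies whose stepwise path skips scans."""
    for name, s in strategies.items():
        step = total_cost_cents(utilization(cohort130, s, "stepwise"), unit_costs)
        uni = total_cost_cents(utilization(cohort130, s, "universal"), unit_costs)
        assert uni >= step
        if name in ("mpmri_or_pet", "psad_and_mpmri"):
            assert uni > step
        else:
            assert uni == step
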