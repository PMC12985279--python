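"""Cost allocation for triage strategies.

Two paradigms decide which procedures are billed:

* **stepwise** — downstream tests are billed only for patients reaching
  that step.  Every patient gets the screening PSA assay; for the
  combined strategies, PET is billed only for mpMRI-negative /
  PET-positive patients (``mpmri_or_pet``) and mpMRI only for patients
  with elevated PSA density (``psad_and_mpmri``).  Every referred
  patient incurs one fusion biopsy plus one pathology exam.
* **universal** — a sensitivity analysis in which every test a strategy
  consults is billed for every patient.

All arithmetic is in integer euro-cents; totals are exact and rounded
to whole EUR only by the report layer.  The PSA assay count per patient
is a config knob (``psa_multiplier``, default 1): enrolment protocols
may repeat the assay, but the costed diagnostic pathway bills it once.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

from .cohort import Cohort, UnitCostTable, is_cspca
from .strategies import TriageStrategy, contingency

logger = logging.getLogger(__name__)

__all__ = [
    "AllocationParadigm",
    "TestUtilization",
    "CostSummary",
    "utilization",
    "total_cost",
    "total_cost_cents",
    "cost_per_detection",
    "cost_summary",
    "per_patient_cost_cents",
    "round_eur",
]


class AllocationParadigm(str, enum.Enum):
    """How procedure counts are attributed to a strategy."""

    STEPWISE = "stepwise"
    UNIVERSAL = "universal"

    @classmethod
    def coerce(cls, value: "AllocationParadigm | str") -> "AllocationParadigm":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown paradigm {value!r}; expected 'stepwise' or 'universal'"
            ) from None


@dataclass(frozen=True)
class TestUtilization:
    """Procedure counts for a strategy on a cohort.

    Every biopsy session is followed by exactly one pathology exam, so
    ``n_biopsy == n_pathology`` always.
    """

    __test__ = False  # not a test class despite the name

    n_psa: int
    n_mpmri: int
    n_pet: int
    n_biopsy: int
    n_pathology: int

    def __post_init__(self) -> None:
        if min(self.n_psa, self.n_mpmri, self.n_pet, self.n_biopsy, self.n_pathology) < 0:
            raise ValueError("utilization counts must be nonnegative")
        if self.n_biopsy != self.n_pathology:
            raise ValueError("every biopsy has exactly one pathology exam")

    def as_dict(self) -> dict[str, int]:
        return {
            "psa": self.n_psa,
            "mpmri": self.n_mpmri,
            "pet": self.n_pet,
            "biopsy": self.n_biopsy,
            "pathology": self.n_pathology,
        }


@dataclass(frozen=True)
class CostSummary:
    """Total and per-detection cost of one strategy on one cohort."""

    total_cost_cents: int
    cost_per_cspca: Optional[float]  # EUR per detected case; None if 0 detected
    utilization: TestUtilization

    @property
    def total_cost_eur(self) -> float:
        return self.total_cost_cents / 100


def round_eur(value_eur: float) -> int:
    """Round to whole EUR, half away from zero (116,057.5 -> 116,058)."""
    return int(Decimal(repr(value_eur)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _stepwise_imaging(strategy: TriageStrategy, record) -> frozenset[str]:
    if strategy.stepwise_plan is None:
        raise ValueError(
            f"strategy {strategy.name!r} has no stepwise plan; "
            "use universal allocation or supply stepwise_plan"
        )
    return strategy.stepwise_plan(record)


def utilization(
    cohort: Cohort,
    strategy: TriageStrategy,
    paradigm: AllocationParadigm | str = AllocationParadigm.STEPWISE,
    *,
    psa_multiplier: int = 1,
) -> TestUtilization:
    """Count procedures performed for ``strategy`` under ``paradigm``."""
    paradigm = AllocationParadigm.coerce(paradigm)
    if psa_multiplier != 1:
        logger.warning(
            "psa_multiplier=%d: enrolment protocols may repeat the PSA assay, "
            "but strategy totals reconcile with one per patient",
            psa_multiplier,
        )
    n = cohort.n
    n_biopsy = sum(strategy.refers(r) for r in cohort)
    n_psa = n * psa_multiplier
    if paradigm is AllocationParadigm.UNIVERSAL:
        n_mpmri = n if "mpmri" in strategy.required_tests else 0
        n_pet = n if "pet" in strategy.required_tests else 0
    else:
        n_mpmri = n_pet = 0
        for r in cohort:
            performed = _stepwise_imaging(strategy, r)
            n_mpmri += "mpmri" in performed
            n_pet += "pet" in performed
    return TestUtilization(n_psa, n_mpmri, n_pet, n_biopsy, n_biopsy)


def total_cost_cents(util: TestUtilization, costs: UnitCostTable) -> int:
    """Exact total cost in euro-cents: sum of count x unit cost."""
    return (
        util.n_psa * costs.cents("psa")
        + util.n_mpmri * costs.cents("mpmri")
        + util.n_pet * costs.cents("pet")
        + util.n_biopsy * costs.cents("biopsy")
        + util.n_pathology * costs.cents("pathology")
    )


def total_cost(util: TestUtilization, costs: UnitCostTable) -> float:
    """Total cost in EUR (exact cents / 100; round only for display)."""
    return total_cost_cents(util, costs) / 100


def cost_per_detection(total_eur: float, detected: int) -> Optional[float]:
    """Cost per csPCa detected (EUR); ``None`` when nothing is detected."""
    if detected < 0:
        raise ValueError("detected must be >= 0")
    if detected == 0:
        return None
    return total_eur / detected


def per_patient_cost_cents(
    cohort: Cohort,
    strategy: TriageStrategy,
    costs: UnitCostTable,
    paradigm: AllocationParadigm | str = AllocationParadigm.STEPWISE,
    *,
    psa_multiplier: int = 1,
) -> list[int]:
    """Individually incurred cost of each patient, in cents.

    The per-patient ledger sums to the utilization-based total; it is
    what the paired bootstrap resamples.
    """
    paradigm = AllocationParadigm.coerce(paradigm)
    base = psa_multiplier * costs.cents("psa")
    biopsy_set = costs.cents("biopsy") + costs.cents("pathology")
    out = []
    for r in cohort:
        c = base
        if paradigm is AllocationParadigm.UNIVERSAL:
            imaging = strategy.required_tests - {"psa"}
        else:
            imaging = _stepwise_imaging(strategy, r)
        for proc in imaging:
            c += costs.cents(proc)
        if strategy.refers(r):
            c += biopsy_set
        out.append(c)
    return out


def cost_summary(
    cohort: Cohort,
    strategy: TriageStrategy,
    costs: UnitCostTable,
    paradigm: AllocationParadigm | str = AllocationParadigm.STEPWISE,
    *,
    psa_multiplier: int = 1,
) -> CostSummary:
    """Utilization, total cost and cost per detection for one strategy."""
    util = utilization(cohort, strategy, paradigm, psa_multiplier=psa_multiplier)
    cents = total_cost_cents(util, costs)
    detected = contingency(cohort, strategy).tp
    return CostSummary(
        total_cost_cents=cents,
        cost_per_cspca=cost_per_detection(cents / 100, detected),
        utilization=util,
    )
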