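"""Triage strategies and their diagnostic performance.

A triage strategy is a deterministic binary rule deciding which patients
are referred to fusion biopsy.  Six built-in strategies are frozen:

========================  ==================================================
name                      referral rule
========================  ==================================================
``biopsy_all``            every patient
``psad``                  PSA density > 0.15 ng/mL/cc (strict)
``mpmri``                 PI-RADS >= 3 on mpMRI
``pet``                   PRIMARY score >= 3 on PSMA-PET
``mpmri_or_pet``          mpMRI positive OR PSMA-PET positive
``psad_and_mpmri``        PSAD > 0.15 AND mpMRI positive
========================  ==================================================

Against the csPCa reference standard (ISUP >= 2) each strategy yields a
2x2 contingency table, the usual diagnostic metrics, the number needed
to biopsy (NNT = biopsies / csPCa detected) and the count of csPCa
missed relative to biopsying everyone.

A rule consulting a missing imaging score classifies the patient as not
referred (conservative) and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, TYPE_CHECKING

from .cohort import Cohort, PatientRecord, is_cspca

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import UnitCostTable
    from .costs import AllocationParadigm, CostSummary

logger = logging.getLogger(__name__)

__all__ = [
    "TriageStrategy",
    "ContingencyTable",
    "DiagnosticMetrics",
    "StrategySummary",
    "builtin_strategies",
    "get_strategy",
    "register_strategy",
    "contingency",
    "diagnostic_metrics",
    "nnt",
    "summarize_strategy",
]

#: PSAD referral threshold, ng/mL/cc; ties are *not* referred.
PSAD_THRESHOLD = 0.15
#: Minimum PI-RADS score counted as mpMRI-positive.
PIRADS_POSITIVE = 3
#: Minimum PRIMARY score counted as PET-positive.
PRIMARY_POSITIVE = 3


def _warn_missing(record: PatientRecord, test: str) -> None:
    logger.warning(
        "patient %s: %s score missing; treated as negative (not referred by rules needing it)",
        record.patient_id,
        test,
    )


def mri_positive(record: PatientRecord) -> bool:
    """PI-RADS >= 3; missing score counts as negative (warned)."""
    if record.pirads is None:
        _warn_missing(record, "pirads")
        return False
    return record.pirads >= PIRADS_POSITIVE


def pet_positive(record: PatientRecord) -> bool:
    """PRIMARY >= 3; missing score counts as negative (warned)."""
    if record.primary_score is None:
        _warn_missing(record, "primary_score")
        return False
    return record.primary_score >= PRIMARY_POSITIVE


def psad_positive(record: PatientRecord) -> bool:
    """PSAD strictly above 0.15 ng/mL/cc."""
    return record.psad > PSAD_THRESHOLD


@dataclass(frozen=True)
class TriageStrategy:
    """A named binary biopsy-referral rule.

    ``required_tests`` lists the procedures the rule consults (all rules
    implicitly consume the screening PSA assay).  ``stepwise_plan`` maps
    a patient to the set of imaging procedures actually performed under
    stepwise cost allocation; it is ``None`` for custom strategies,
    which then only support universal allocation.
    """

    name: str
    label: str
    rule: Callable[[PatientRecord], bool]
    required_tests: frozenset[str]
    stepwise_plan: Optional[Callable[[PatientRecord], frozenset[str]]] = None

    def refers(self, record: PatientRecord) -> bool:
        return bool(self.rule(record))


_NO_IMAGING = frozenset()
_MRI = frozenset({"mpmri"})
_PET = frozenset({"pet"})
_MRI_PET = frozenset({"mpmri", "pet"})


def _stepwise_or(record: PatientRecord) -> frozenset[str]:
    # mpMRI for everyone; PET billed only when mpMRI is negative but PET
    # positive — the stated accounting rule, kept although one cannot
    # know PET is positive before scanning.
    if not mri_positive(record) and pet_positive(record):
        return _MRI_PET
    return _MRI


def _stepwise_and(record: PatientRecord) -> frozenset[str]:
    # mpMRI performed only in patients with elevated PSA density.
    return _MRI if psad_positive(record) else _NO_IMAGING


_BUILTINS: dict[str, TriageStrategy] = {}


def register_strategy(strategy: TriageStrategy, *, overwrite: bool = False) -> None:
    """Register a custom strategy by name; the six built-ins are frozen."""
    if strategy.name in _BUILTINS and not overwrite:
        raise ValueError(f"strategy {strategy.name!r} already registered")
    if strategy.name in {s.name for s in builtin_strategies()}:
        raise ValueError(f"built-in strategy {strategy.name!r} cannot be replaced")
    _BUILTINS[strategy.name] = strategy


def builtin_strategies() -> list[TriageStrategy]:
    """The six frozen triage strategies, in canonical (reporting) order."""
    return [
        TriageStrategy(
            "biopsy_all", "Biopsy-all", lambda r: True, frozenset({"psa"}),
            lambda r: _NO_IMAGING,
        ),
        TriageStrategy(
            "psad", "PSAD > 0.15", psad_positive, frozenset({"psa"}),
            lambda r: _NO_IMAGING,
        ),
        TriageStrategy(
            "mpmri", "mpMRI+ (PI-RADS >= 3)", mri_positive,
            frozenset({"psa", "mpmri"}), lambda r: _MRI,
        ),
        TriageStrategy(
            "pet", "PSMA-PET+", pet_positive, frozenset({"psa", "pet"}),
            lambda r: _PET,
        ),
        TriageStrategy(
            "mpmri_or_pet", "mpMRI+ OR PET+",
            lambda r: mri_positive(r) or pet_positive(r),
            frozenset({"psa", "mpmri", "pet"}), _stepwise_or,
        ),
        TriageStrategy(
            "psad_and_mpmri", "PSAD > 0.15 AND mpMRI+",
            lambda r: psad_positive(r) and mri_positive(r),
            frozenset({"psa", "mpmri"}), _stepwise_and,
        ),
    ]


def get_strategy(name: str) -> TriageStrategy:
    """Look up a strategy by name among built-ins and registered customs."""
    for s in builtin_strategies():
        if s.name == name:
            return s
    if name in _BUILTINS:
        return _BUILTINS[name]
    known = [s.name for s in builtin_strategies()] + list(_BUILTINS)
    raise KeyError(f"unknown strategy {name!r}; known: {', '.join(known)}")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of referral decision vs. the csPCa reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def referred(self) -> int:
        return self.tp + self.fp

    @property
    def cspca(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy as proportions.

    A metric whose denominator is zero is ``None`` ("not defined"), e.g.
    NPV under biopsy-all where nobody is spared biopsy.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float


@dataclass(frozen=True)
class StrategySummary:
    """One report row for a strategy: counts, NNT and costs.

    ``nnt`` is kept at full precision; display rounding (1 decimal) is
    done by the report layer.  ``cost_per_cspca`` is ``None`` when no
    csPCa is detected.
    """

    name: str
    label: str
    biopsies: int
    cspca_detected: int
    nnt: Optional[float]
    biopsies_avoided: int
    cspca_missed: int
    total_cost_cents: int
    cost_per_cspca: Optional[float]

    @property
    def total_cost_eur(self) -> float:
        return self.total_cost_cents / 100


def contingency(cohort: Cohort, strategy: TriageStrategy) -> ContingencyTable:
    """Cross-classify referral decisions against csPCa status."""
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    tp = fp = fn = tn = 0
    for r in cohort:
        referred = strategy.refers(r)
        cs = is_cspca(r)
        if referred and cs:
            tp += 1
        elif referred:
            fp += 1
        elif cs:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Diagnostic accuracy metrics from a 2x2 table.

    Zero-denominator ratios come back as ``None``; an all-zero table is
    an error because accuracy itself is undefined.
    """
    if table.n == 0:
        raise ValueError("all-zero contingency table")
    return DiagnosticMetrics(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy=(table.tp + table.tn) / table.n,
    )


def nnt(biopsies: int, detected: int) -> Optional[float]:
    """Number needed to biopsy: biopsies per csPCa detected.

    Returns ``None`` (undefined) when nothing is detected.  Full
    precision; reports round to one decimal.
    """
    if not (biopsies >= detected >= 0):
        raise ValueError(f"need biopsies >= detected >= 0, got {biopsies}, {detected}")
    if detected == 0:
        return None
    return biopsies / detected


def summarize_strategy(
    cohort: Cohort,
    strategy: TriageStrategy,
    costs: "UnitCostTable",
    paradigm: "AllocationParadigm | str" = "stepwise",
    *,
    psa_multiplier: int = 1,
) -> StrategySummary:
    """Evaluate one strategy end to end: counts, NNT, missed cases, costs."""
    from .costs import cost_summary  # local import to avoid a cycle

    table = contingency(cohort, strategy)
    cs = cost_summary(cohort, strategy, costs, paradigm, psa_multiplier=psa_multiplier)
    detected = table.tp
    return StrategySummary(
        name=strategy.name,
        label=strategy.label,
        biopsies=table.referred,
        cspca_detected=detected,
        nnt=nnt(table.referred, detected),
        biopsies_avoided=cohort.n - table.referred,
        cspca_missed=cohort.n_cspca - detected,
        total_cost_cents=cs.total_cost_cents,
        cost_per_cspca=cs.cost_per_cspca,
    )
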