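"""Pairwise incremental cost-effectiveness of triage strategies.

For a candidate strategy against a comparator on the same cohort:

* ``delta_e`` — additional csPCa detected (candidate − reference);
* ``delta_c`` — additional total cost in EUR, computed from each arm's
  whole-EUR-rounded total (report convention; exact-cent deltas are
  also carried);
* ICER = ``delta_c / delta_e`` when the candidate detects more, with
  dominance statuses otherwise;
* INB(WTP) = ``(delta_e × WTP − delta_c) / n`` — the incremental net
  benefit **per patient**; a positive INB means the candidate is
  cost-effective at that willingness-to-pay.

INB is affine in WTP, so a strategy with ``delta_e == 0`` has the same
INB at every threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import Cohort, UnitCostTable
from .costs import AllocationParadigm, cost_summary, round_eur
from .strategies import TriageStrategy, contingency, get_strategy

__all__ = [
    "IcerStatus",
    "IcerResult",
    "PairwiseComparison",
    "WtpGrid",
    "DEFAULT_WTP_GRID",
    "icer",
    "inb",
    "compare_pair",
    "compare_all",
]

#: Default willingness-to-pay thresholds, EUR per additional csPCa detected.
DEFAULT_WTP_GRID = (5000.0, 10000.0, 20000.0)


class IcerStatus(str, enum.Enum):
    """Interpretation of an incremental comparison.

    ``ratio``            candidate detects more at extra cost: report ΔC/ΔE.
    ``dominant``         candidate detects more at no extra cost.
    ``no_delta_effect``  equal detection; no ratio (cost difference decides).
    ``dominated``        equal detection at strictly higher cost.
    ``less_effective``   candidate detects fewer cases; no ratio reported.
    """

    RATIO = "ratio"
    DOMINANT = "dominant"
    NO_DELTA_EFFECT = "no_delta_effect"
    DOMINATED = "dominated"
    LESS_EFFECTIVE = "less_effective"


@dataclass(frozen=True)
class IcerResult:
    status: IcerStatus
    value: Optional[float] = None  # EUR per extra csPCa, when status == RATIO

    def display(self) -> str:
        if self.status is IcerStatus.RATIO:
            return str(round_eur(self.value))
        if self.status is IcerStatus.NO_DELTA_EFFECT:
            return "- (no Δ effect)"
        if self.status is IcerStatus.LESS_EFFECTIVE:
            return "N/A (less eff.)"
        return self.status.value


def validate_wtp_grid(grid: Sequence[float]) -> tuple[float, ...]:
    """A WTP grid must be positive and strictly increasing."""
    grid = tuple(float(w) for w in grid)
    if not grid or any(w <= 0 for w in grid):
        raise ValueError("WTP values must be positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("WTP grid must be strictly increasing")
    return grid


WtpGrid = tuple


def icer(delta_c: float, delta_e: int) -> IcerResult:
    """Incremental cost-effectiveness ratio with dominance handling.

    ΔE > 0 with ΔC > 0 gives a ratio; ΔE > 0 with ΔC <= 0 is dominant;
    ΔE = 0 yields no ratio (``no_delta_effect`` when cost-saving or
    cost-neutral, ``dominated`` when costlier); ΔE < 0 is
    ``less_effective`` and no ratio is reported.
    """
    if delta_e > 0:
        if delta_c <= 0:
            return IcerResult(IcerStatus.DOMINANT)
        return IcerResult(IcerStatus.RATIO, delta_c / delta_e)
    if delta_e == 0:
        if delta_c > 0:
            return IcerResult(IcerStatus.DOMINATED)
        return IcerResult(IcerStatus.NO_DELTA_EFFECT)
    return IcerResult(IcerStatus.LESS_EFFECTIVE)


def inb(delta_c: float, delta_e: float, wtp: float, n: int) -> float:
    """Incremental net benefit per patient: ((ΔE × WTP) − ΔC) / n."""
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    if wtp < 0:
        raise ValueError("WTP must be nonnegative")
    return (delta_e * wtp - delta_c) / n


@dataclass(frozen=True)
class PairwiseComparison:
    """Incremental comparison of ``candidate`` vs ``reference``.

    ``delta_c`` follows the report convention (difference of whole-EUR
    arm totals); ``delta_c_exact`` keeps the cent-exact difference.
    ``inb_per_patient`` maps each WTP to EUR per patient (full
    precision); ``inb_cohort_total`` is the undivided cohort figure.
    """

    reference: str
    candidate: str
    delta_e: int
    delta_c: int
    delta_c_exact: float
    icer: IcerResult
    inb_per_patient: dict[float, float]
    inb_cohort_total: dict[float, float]
    n: int
    candidate_cost_eur: int = 0
    reference_cost_eur: int = 0
    candidate_detected: int = 0
    reference_detected: int = 0


def compare_pair(
    cohort: Cohort,
    candidate: TriageStrategy,
    reference: TriageStrategy,
    costs: UnitCostTable,
    paradigm: AllocationParadigm | str = AllocationParadigm.STEPWISE,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    *,
    psa_multiplier: int = 1,
) -> PairwiseComparison:
    """Evaluate both arms on the cohort and form the incremental row."""
    wtp_grid = validate_wtp_grid(wtp_grid)
    cand_cs = cost_summary(cohort, candidate, costs, paradigm, psa_multiplier=psa_multiplier)
    ref_cs = cost_summary(cohort, reference, costs, paradigm, psa_multiplier=psa_multiplier)
    cand_det = contingency(cohort, candidate).tp
    ref_det = contingency(cohort, reference).tp

    cand_eur = round_eur(cand_cs.total_cost_eur)
    ref_eur = round_eur(ref_cs.total_cost_eur)
    delta_e = cand_det - ref_det
    delta_c = cand_eur - ref_eur
    delta_c_exact = (cand_cs.total_cost_cents - ref_cs.total_cost_cents) / 100

    return PairwiseComparison(
        reference=reference.name,
        candidate=candidate.name,
        delta_e=delta_e,
        delta_c=delta_c,
        delta_c_exact=delta_c_exact,
        icer=icer(delta_c, delta_e),
        inb_per_patient={w: inb(delta_c, delta_e, w, cohort.n) for w in wtp_grid},
        inb_cohort_total={w: delta_e * w - delta_c for w in wtp_grid},
        n=cohort.n,
        candidate_cost_eur=cand_eur,
        reference_cost_eur=ref_eur,
        candidate_detected=cand_det,
        reference_detected=ref_det,
    )


def compare_all(
    cohort: Cohort,
    strategies: Sequence[TriageStrategy],
    reference: str,
    costs: UnitCostTable,
    paradigm: AllocationParadigm | str = AllocationParadigm.STEPWISE,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    *,
    psa_multiplier: int = 1,
) -> list[PairwiseComparison]:
    """Compare every non-reference strategy against ``reference``.

    Rows come back in the order of ``strategies`` (deterministic).
    """
    names = [s.name for s in strategies]
    if reference not in names:
        raise KeyError(f"reference strategy {reference!r} not among {names}")
    ref = strategies[names.index(reference)]
    return [
        compare_pair(
            cohort, s, ref, costs, paradigm, wtp_grid, psa_multiplier=psa_multiplier
        )
        for s in strategies
        if s.name != reference
    ]
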