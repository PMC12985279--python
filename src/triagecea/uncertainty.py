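"""Uncertainty quantification for incremental comparisons.

Three routes are provided, mirroring common practice in trial-based
cost-effectiveness analysis:

* **analytic, "as published"** — the effect difference gets a binomial
  SE (two arms at the cohort prevalence on the same n) and arm costs a
  coefficient-of-variation SE combined in quadrature; the ICER then gets
  a Fieller interval and the INB a delta-method interval.  These are
  approximations: the paired design's between-arm correlation is not
  modelled.
* **Fieller's theorem** — the confidence set for a ratio of jointly
  normal quantities; it can be a bounded interval, a half-line to
  +/-infinity, or the whole real line when the effect difference is
  indistinguishable from zero.
* **paired patient-level bootstrap** — patients are resampled with
  replacement and *both* strategies are re-evaluated on each replicate
  cohort, preserving within-patient correlation; yields percentile CIs
  and the cost-effectiveness acceptability curve CEAC(WTP) = fraction
  of replicates with INB > 0.  The bootstrap is the preferred
  estimator.

The printed delta-method SE formula carries ``+2*WTP*cov(dC,dE)`` while
the variance algebra of ``WTP*dE - dC`` yields a minus sign on the
covariance; both conventions are available via ``cov_sign`` and neither
is asserted as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import Cohort, UnitCostTable, is_cspca
from .costs import AllocationParadigm, per_patient_cost_cents
from .incremental import DEFAULT_WTP_GRID, PairwiseComparison, validate_wtp_grid
from .strategies import TriageStrategy

__all__ = [
    "UncertaintySpec",
    "IntervalEstimate",
    "BootstrapResult",
    "se_delta_effect",
    "se_cost",
    "combine_arm_ses",
    "fieller_ci",
    "inb_ci",
    "bootstrap_pairwise",
    "analytic_intervals",
]


@dataclass(frozen=True)
class UncertaintySpec:
    """Assumptions driving the analytic (non-bootstrap) intervals.

    cost_cv
        Coefficient of variation of each arm's total cost (default
        0.175, the midpoint of the 15–20% range typical of diagnostic
        costing studies).
    cov_ce
        Covariance of (ΔCost, ΔcsPCa) in EUR·cases; default 0, may be
        bootstrap-estimated and injected.
    cov_sign
        +1 applies the covariance term as printed in the SE_INB
        formula; -1 applies the textbook variance-algebra sign.
    """

    cost_cv: float = 0.175
    cov_ce: float = 0.0
    alpha: float = 0.05
    z: float = 1.96
    cov_sign: int = +1

    def __post_init__(self) -> None:
        if self.cost_cv < 0:
            raise ValueError("cost_cv must be >= 0")
        if self.cov_sign not in (+1, -1):
            raise ValueError("cov_sign must be +1 or -1")


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a confidence interval.

    ``lower``/``upper`` may be -inf/+inf (unbounded Fieller sets);
    ``status`` is ``"ok"`` for a usable interval, ``"undefined"`` when
    no interval exists (complex roots with a bounded-type quadratic).
    """

    point: float
    lower: float
    upper: float
    method: str  # fieller | delta | bootstrap_percentile
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok" and math.isfinite(self.lower) and math.isfinite(self.upper):
            if not (self.lower <= self.point <= self.upper):
                raise ValueError(
                    f"interval [{self.lower}, {self.upper}] must contain point {self.point}"
                )


def se_delta_effect(p: float, n: int) -> float:
    """SE of the csPCa-count difference between two strategies.

    Two-arm binomial model at shared prevalence ``p`` on the same ``n``,
    scaled to counts: ``n * sqrt(2 p (1-p) / n) = sqrt(2 p (1-p) n)``.
    At p=0.2, n=130 this is sqrt(41.6) ~ 6.45 cases.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 < p < 1):
        raise ValueError(f"prevalence must be in (0, 1), got {p}")
    return math.sqrt(2 * p * (1 - p) * n)


def se_cost(total_cost: float, cv: float) -> float:
    """SE of one arm's total cost under a coefficient-of-variation model."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return cv * total_cost


def combine_arm_ses(se_a: float, se_b: float, cov: float = 0.0) -> float:
    """SE of a difference of two arm totals: sqrt(se_a² + se_b² − 2 cov)."""
    var = se_a**2 + se_b**2 - 2 * cov
    if var < 0:
        raise ValueError(f"negative variance from cov={cov}")
    return math.sqrt(var)


def _zvalue(alpha: float, z: Optional[float]) -> float:
    return float(norm.ppf(1 - alpha / 2)) if z is None else z


def fieller_ci(
    delta_c: float,
    delta_e: float,
    se_c: float,
    se_e: float,
    cov: float = 0.0,
    alpha: float = 0.05,
    z: Optional[float] = 1.96,
) -> IntervalEstimate:
    """Fieller confidence set for the ratio ΔC/ΔE.

    Roots of ``(ΔE² − z² se_e²) R² − 2 (ΔE ΔC − z² cov) R +
    (ΔC² − z² se_c²) = 0``.  When ``ΔE² − z² se_e² <= 0`` the effect is
    not distinguishable from zero and the set is unbounded: the branch
    containing the point ratio is reported with an infinite endpoint
    (or the whole line when the roots are complex).  With all SEs zero
    the interval collapses to the point.
    """
    if se_c < 0 or se_e < 0:
        raise ValueError("standard errors must be >= 0")
    zz = _zvalue(alpha, z)
    if delta_e == 0:
        raise ZeroDivisionError("point ratio undefined for delta_e = 0")
    point = delta_c / delta_e

    if se_c == 0 and se_e == 0 and cov == 0:
        return IntervalEstimate(point, point, point, "fieller")

    a = delta_e**2 - zz**2 * se_e**2
    b = -2 * (delta_e * delta_c - zz**2 * cov)
    c = delta_c**2 - zz**2 * se_c**2
    disc = b**2 - 4 * a * c

    if a > 0:
        if disc < 0:
            return IntervalEstimate(point, math.nan, math.nan, "fieller", status="undefined")
        r1 = (-b - math.sqrt(disc)) / (2 * a)
        r2 = (-b + math.sqrt(disc)) / (2 * a)
        return IntervalEstimate(point, min(r1, r2), max(r1, r2), "fieller")

    # a <= 0: unbounded confidence set
    if disc < 0 or a == 0:
        return IntervalEstimate(point, -math.inf, math.inf, "fieller")
    r1, r2 = sorted(((-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)))
    # set is (-inf, r1] U [r2, +inf); report the branch holding the point
    if point >= r2:
        return IntervalEstimate(point, r2, math.inf, "fieller")
    return IntervalEstimate(point, -math.inf, r1, "fieller")


def inb_ci(
    delta_c: float,
    delta_e: float,
    wtp: float,
    n: int,
    se_c: float,
    se_e: float,
    cov: float = 0.0,
    *,
    z: float = 1.96,
    cov_sign: int = +1,
) -> IntervalEstimate:
    """Delta-method interval for the per-patient INB.

    ``SE_INB = sqrt(se_c² + (WTP se_e)² + cov_sign · 2 WTP cov)`` on the
    cohort-total scale, then divided by n for the per-patient interval
    ``point ± z · SE_INB / n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    var = se_c**2 + (wtp * se_e) ** 2 + cov_sign * 2 * wtp * cov
    if var < 0:
        raise ValueError(f"negative INB variance: cov={cov} (sign {cov_sign:+d}) too large")
    point = (delta_e * wtp - delta_c) / n
    half = z * math.sqrt(var) / n
    return IntervalEstimate(point, point - half, point + half, "delta")


def analytic_intervals(
    comparison: PairwiseComparison,
    spec: UncertaintySpec,
    prevalence: float,
) -> dict:
    """Fieller ICER interval and delta-method INB intervals for one row.

    Arm-cost SEs are ``cost_cv`` times each arm total, combined in
    quadrature; the effect SE is the shared-prevalence binomial model.
    Labelled "approximate, as published" — the bootstrap is preferred.
    """
    se_e = se_delta_effect(prevalence, comparison.n)
    se_dc = combine_arm_ses(
        se_cost(comparison.candidate_cost_eur, spec.cost_cv),
        se_cost(comparison.reference_cost_eur, spec.cost_cv),
    )
    out: dict = {"se_delta_e": se_e, "se_delta_c": se_dc}
    if comparison.delta_e != 0:
        out["icer_fieller"] = fieller_ci(
            comparison.delta_c, comparison.delta_e, se_dc, se_e, spec.cov_ce,
            spec.alpha, spec.z,
        )
    out["inb_delta"] = {
        w: inb_ci(
            comparison.delta_c, comparison.delta_e, w, comparison.n,
            se_dc, se_e, spec.cov_ce, z=spec.z, cov_sign=spec.cov_sign,
        )
        for w in comparison.inb_per_patient
    }
    return out


# ---------------------------------------------------------------------------
# Paired patient-level bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Replicate draws and derived summaries of a paired bootstrap.

    Each replicate resamples patients with replacement and evaluates
    both strategies on the same replicate cohort (two-arm reformatting
    of a paired diagnostic design).  ``icer_draws`` holds ΔC/ΔE for
    replicates with ΔE != 0 only; ``prop_zero_delta_e`` reports how
    often the ratio was undefined.
    """

    candidate: str
    reference: str
    B: int
    seed: Optional[int]
    delta_e_draws: np.ndarray
    delta_c_draws: np.ndarray  # EUR
    inb_draws: dict[float, np.ndarray]  # per patient, EUR
    icer_draws: np.ndarray
    prop_zero_delta_e: float
    inb_ci: dict[float, IntervalEstimate] = field(default_factory=dict)
    delta_e_ci: Optional[IntervalEstimate] = None
    delta_c_ci: Optional[IntervalEstimate] = None
    ceac: dict[float, float] = field(default_factory=dict)


def _percentile_interval(point: float, draws: np.ndarray, alpha: float) -> IntervalEstimate:
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    # guard: a point outside the percentile band can occur in tiny-B runs
    return IntervalEstimate(
        point, min(float(lo), point), max(float(hi), point), "bootstrap_percentile"
    )


def bootstrap_pairwise(
    cohort: Cohort,
    candidate: TriageStrategy,
    reference: TriageStrategy,
    costs: UnitCostTable,
    paradigm: AllocationParadigm | str = AllocationParadigm.STEPWISE,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    B: int = 2000,
    seed: Optional[int] = None,
    *,
    psa_multiplier: int = 1,
    alpha: float = 0.05,
    indices: Optional[np.ndarray] = None,
) -> BootstrapResult:
    """Seeded paired bootstrap of (ΔE, ΔC, INB) with percentile CIs and CEAC.

    ``indices`` may supply a precomputed ``(B, n)`` replicate index
    matrix (e.g. ``np.arange(n)[None, :]`` reproduces the point
    estimates exactly); otherwise indices are drawn from
    ``numpy.random.default_rng(seed)``.  Identical ``seed`` and ``B``
    give bit-identical output.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    wtp_grid = validate_wtp_grid(wtp_grid)
    n = cohort.n

    cs = np.array([is_cspca(r) for r in cohort], dtype=np.int64)
    det_cand = cs * np.array([candidate.refers(r) for r in cohort], dtype=np.int64)
    det_ref = cs * np.array([reference.refers(r) for r in cohort], dtype=np.int64)
    cost_cand = np.array(
        per_patient_cost_cents(cohort, candidate, costs, paradigm, psa_multiplier=psa_multiplier),
        dtype=np.int64,
    )
    cost_ref = np.array(
        per_patient_cost_cents(cohort, reference, costs, paradigm, psa_multiplier=psa_multiplier),
        dtype=np.int64,
    )
    # per-patient paired differences: resampling sums over patients
    d_det = det_cand - det_ref
    d_cost = cost_cand - cost_ref

    if indices is None:
        rng = np.random.default_rng(seed)
        indices = rng.integers(0, n, size=(B, n))
    else:
        indices = np.asarray(indices)
        B = indices.shape[0]

    delta_e = d_det[indices].sum(axis=1)
    delta_c = d_cost[indices].sum(axis=1) / 100.0

    inb_draws = {w: (delta_e * w - delta_c) / n for w in wtp_grid}

    nonzero = delta_e != 0
    icer_draws = delta_c[nonzero] / delta_e[nonzero]
    prop_zero = 1.0 - nonzero.mean()

    point_e = int(d_det.sum())
    point_c = d_cost.sum() / 100.0
    res = BootstrapResult(
        candidate=candidate.name,
        reference=reference.name,
        B=B,
        seed=seed,
        delta_e_draws=delta_e,
        delta_c_draws=delta_c,
        inb_draws=inb_draws,
        icer_draws=icer_draws,
        prop_zero_delta_e=float(prop_zero),
        delta_e_ci=_percentile_interval(point_e, delta_e, alpha),
        delta_c_ci=_percentile_interval(point_c, delta_c, alpha),
    )
    for w in wtp_grid:
        point_inb = (point_e * w - point_c) / n
        res.inb_ci[w] = _percentile_interval(point_inb, inb_draws[w], alpha)
        res.ceac[w] = float((inb_draws[w] > 0).mean())
    return res
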