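"""Synthetic cohorts: the deterministic reference fixture and a stochastic generator.

``fixture_cohort`` builds, without any randomness, a 130-patient cohort
(26 csPCa, prevalence 0.2) whose per-strategy (biopsied, detected)
margins are, simultaneously for all six built-in strategies:

    biopsy_all (130, 26), psad (61, 17), mpmri (34, 17), pet (25, 18),
    mpmri_or_pet (42, 22), psad_and_mpmri (20, 12)

The margins pin down the mpMRI x PET joint by inclusion–exclusion
(csPCa: both 13, MRI-only 4, PET-only 5, neither 4; non-csPCa: both 4,
MRI-only 13, PET-only 3, neither 84).  Cells the margins do not
determine (which patients carry elevated PSA density) are completed by
a greedy assignment in a canonical patient order; any consistent
completion reproduces every printed margin, so the choice is free but
frozen for reproducibility.  PSAD values keep a >= 0.01 margin from the
0.15 referral threshold.

``simulate_cohort`` draws cohorts with configurable prevalence,
per-test sensitivity/specificity and an mpMRI–PET tetrachoric-style
dependence, for property and coverage testing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import Cohort, PatientRecord

__all__ = [
    "MarginSpec",
    "PerformanceSpec",
    "fixture_cohort",
    "simulate_cohort",
]

#: Canonical per-strategy (biopsied, detected) margins of the reference cohort.
FIXTURE_MARGINS: dict[str, tuple[int, int]] = {
    "biopsy_all": (130, 26),
    "psad": (61, 17),
    "mpmri": (34, 17),
    "pet": (25, 18),
    "mpmri_or_pet": (42, 22),
    "psad_and_mpmri": (20, 12),
}


@dataclass(frozen=True)
class MarginSpec:
    """Target margins a fixture cohort must satisfy exactly."""

    n: int = 130
    n_cspca: int = 26
    margins: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(FIXTURE_MARGINS)
    )

    def check(self, cohort: Cohort) -> None:
        """Raise if any strategy margin deviates from the spec."""
        from .strategies import builtin_strategies, contingency

        errs = []
        if cohort.n != self.n:
            errs.append(f"n={cohort.n}, expected {self.n}")
        if cohort.n_cspca != self.n_cspca:
            errs.append(f"csPCa={cohort.n_cspca}, expected {self.n_cspca}")
        for s in builtin_strategies():
            want = self.margins.get(s.name)
            if want is None:
                continue
            t = contingency(cohort, s)
            got = (t.referred, t.tp)
            if got != want:
                errs.append(f"{s.name}: (biopsied, detected)={got}, expected {want}")
        if errs:
            raise AssertionError("fixture margins violated: " + "; ".join(errs))


# Deterministic attribute pools; cycled in canonical patient order.
_PSAD_POS = (0.22, 0.31, 0.18, 0.45, 0.27, 0.19, 0.38, 0.24, 0.52, 0.33)
_PSAD_NEG = (0.08, 0.12, 0.05, 0.10, 0.13, 0.07, 0.11, 0.03, 0.09, 0.06)
_PIRADS_POS = (4, 3, 5)
_PIRADS_NEG = (1, 2)
_PRIMARY_POS = (4, 5, 3)
_PRIMARY_NEG = (2, 1)
_ISUP_CS = (2, 3, 4, 5)
_ISUP_BENIGN = (0, 1, 0)


def _build_fixture_rows() -> list[dict]:
    """Joint-cell layout: (csPCa?, MRI+?, PET+?, cell size, PSAD+ quota).

    Within csPCa, 12 of the 17 MRI-positive and 5 of the 9 MRI-negative
    patients carry elevated PSAD (giving the psad margin 17 detected and
    the psad_and_mpmri margin 12); within non-csPCa, 8 of 17 MRI-positive
    and 36 of 87 MRI-negative do (giving 61 elevated in total and the 20
    psad_and_mpmri biopsies).  Quotas are filled greedily from the first
    patient of each block.
    """
    # (cs, mri, pet, count): fixed inclusion–exclusion cells
    cells = [
        (True, True, True, 13),
        (True, True, False, 4),
        (True, False, True, 5),
        (True, False, False, 4),
        (False, True, True, 4),
        (False, True, False, 13),
        (False, False, True, 3),
        (False, False, False, 84),
    ]
    # PSAD+ quotas per (cs, mri) stratum, filled in cell order above
    quotas = {(True, True): 12, (True, False): 5, (False, True): 8, (False, False): 36}

    rows: list[dict] = []
    for cs, mri, pet, count in cells:
        for _ in range(count):
            stratum = (cs, mri)
            psad_pos = quotas[stratum] > 0
            if psad_pos:
                quotas[stratum] -= 1
            rows.append({"cs": cs, "mri": mri, "pet": pet, "psad_pos": psad_pos})
    assert all(v == 0 for v in quotas.values())
    return rows


def fixture_cohort() -> Cohort:
    """The canonical deterministic 130-patient reference cohort.

    Idempotent and bit-stable: no RNG is involved and attribute values
    come from fixed cycles.  An internal margin check runs on every
    build and must never fire.
    """
    rows = _build_fixture_rows()
    pools = {
        "psad_pos": itertools.cycle(_PSAD_POS),
        "psad_neg": itertools.cycle(_PSAD_NEG),
        "pirads_pos": itertools.cycle(_PIRADS_POS),
        "pirads_neg": itertools.cycle(_PIRADS_NEG),
        "primary_pos": itertools.cycle(_PRIMARY_POS),
        "primary_neg": itertools.cycle(_PRIMARY_NEG),
        "isup_cs": itertools.cycle(_ISUP_CS),
        "isup_benign": itertools.cycle(_ISUP_BENIGN),
    }
    records = []
    for i, row in enumerate(rows, start=1):
        records.append(
            PatientRecord(
                patient_id=f"P{i:03d}",
                psad=next(pools["psad_pos" if row["psad_pos"] else "psad_neg"]),
                pirads=next(pools["pirads_pos" if row["mri"] else "pirads_neg"]),
                primary_score=next(pools["primary_pos" if row["pet"] else "primary_neg"]),
                isup=next(pools["isup_cs" if row["cs"] else "isup_benign"]),
            )
        )
    cohort = Cohort.from_records(records)
    MarginSpec().check(cohort)  # must never fire
    return cohort


# ---------------------------------------------------------------------------
# Stochastic generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceSpec:
    """Test-performance parameters of the stochastic cohort generator.

    Defaults are the reference-cohort operating points: prevalence
    26/130; mpMRI sens 17/26, spec 87/104; PET sens 18/26, spec
    97/104; PSAD sens 17/26, spec 60/104.  ``mri_pet_rho`` is a
    correlation-style dependence between mpMRI and PET positivity
    within each disease stratum (0 = conditional independence); its
    feasible range depends on the marginal positivity rates.
    """

    prevalence: float = 26 / 130
    mri_sens: float = 17 / 26
    mri_spec: float = 87 / 104
    pet_sens: float = 18 / 26
    pet_spec: float = 97 / 104
    psad_sens: float = 17 / 26
    psad_spec: float = 60 / 104
    mri_pet_rho: float = 0.25

    def __post_init__(self) -> None:
        probs = {
            "prevalence": self.prevalence,
            "mri_sens": self.mri_sens, "mri_spec": self.mri_spec,
            "pet_sens": self.pet_sens, "pet_spec": self.pet_spec,
            "psad_sens": self.psad_sens, "psad_spec": self.psad_spec,
        }
        for k, v in probs.items():
            if not (0 <= v <= 1):
                raise ValueError(f"{k} must be in [0, 1], got {v}")


def _joint_both_positive(p1: float, p2: float, rho: float) -> float:
    """P(both tests positive) with correlation ``rho`` between indicators.

    Clamped at machine tolerance to the Frechet bounds; infeasible
    ``rho`` raises with the feasible range.
    """
    p11 = p1 * p2 + rho * math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo, hi = max(0.0, p1 + p2 - 1), min(p1, p2)
    if p11 < lo - 1e-12 or p11 > hi + 1e-12:
        denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        if denom == 0:
            rng_txt = "rho must be 0 for degenerate marginals"
        else:
            rng_txt = f"feasible rho in [{(lo - p1 * p2) / denom:.3f}, {(hi - p1 * p2) / denom:.3f}]"
        raise ValueError(f"infeasible mri_pet_rho={rho} for marginals ({p1:.3f}, {p2:.3f}); {rng_txt}")
    return min(max(p11, lo), hi)


def simulate_cohort(
    n: int,
    spec: PerformanceSpec = PerformanceSpec(),
    seed: Optional[int] = None,
) -> Cohort:
    """Draw a cohort of ``n`` patients; reproducible per ``seed``.

    Disease status is Bernoulli(prevalence); mpMRI and PET positivity
    are drawn jointly within each status stratum with dependence
    ``mri_pet_rho``; PSAD positivity is conditionally independent given
    status, and the continuous PSAD value is drawn from one of two
    lognormal families strictly above or below the 0.15 threshold.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)

    cs = rng.random(n) < spec.prevalence

    mri = np.empty(n, dtype=bool)
    pet = np.empty(n, dtype=bool)
    for status, p_m, p_p in (
        (True, spec.mri_sens, spec.pet_sens),
        (False, 1 - spec.mri_spec, 1 - spec.pet_spec),
    ):
        mask = cs == status
        k = int(mask.sum())
        if k == 0:
            continue
        p11 = _joint_both_positive(p_m, p_p, spec.mri_pet_rho)
        u = rng.random(k)
        # cell thresholds: both+, mri-only, pet-only, neither
        c1 = p11
        c2 = c1 + (p_m - p11)
        c3 = c2 + (p_p - p11)
        mri[mask] = u < c2
        pet[mask] = (u < c1) | ((u >= c2) & (u < c3))

    p_psad = np.where(cs, spec.psad_sens, 1 - spec.psad_spec)
    psad_pos = rng.random(n) < p_psad
    # continuous PSAD straddling the 0.15 rule threshold (>= 0.005 margin)
    above = 0.155 + rng.lognormal(mean=-2.2, sigma=0.6, size=n)
    below = 0.145 * rng.beta(2.0, 2.0, size=n)
    psad = np.where(psad_pos, above, below)

    pirads = np.where(mri, rng.integers(3, 6, size=n), rng.integers(1, 3, size=n))
    primary = np.where(pet, rng.integers(3, 6, size=n), rng.integers(1, 3, size=n))
    isup = np.where(cs, rng.integers(2, 6, size=n), rng.integers(0, 2, size=n))

    records = [
        PatientRecord(
            patient_id=f"S{i:06d}",
            psad=float(psad[i]),
            pirads=int(pirads[i]),
            primary_score=int(primary[i]),
            isup=int(isup[i]),
        )
        for i in range(n)
    ]
    return Cohort.from_records(records)
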