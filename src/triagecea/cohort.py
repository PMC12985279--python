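"""Patient-level cohort model for biopsy-triage evaluation.

A cohort is an ordered collection of patients, each carrying the three
triage inputs consulted by the referral rules — PSA density (PSAD,
ng/mL/cc), the mpMRI PI-RADS score (1–5) and the PSMA-PET PRIMARY score
(1–5) — together with the biopsy outcome as an ISUP grade group.  ISUP 0
encodes a benign / negative biopsy; ISUP 1 is cancer that is not
clinically significant; clinically significant prostate cancer (csPCa),
the reference standard throughout the package, is ISUP grade group >= 2.

Imaging scores may be missing (patients with contraindications); the
strategy layer treats a missing score as a negative finding and logs a
warning.  Monetary amounts never live here: unit costs are a separate
table (:class:`UnitCostTable`) consumed by the cost engine, carried as
integer euro-cents internally so that totals are exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "UnitCostTable",
    "Cohort",
    "CohortValidationError",
    "is_cspca",
    "read_cohort",
    "write_cohort",
]

#: ISUP grade group threshold defining clinically significant disease.
CSPCA_ISUP_THRESHOLD = 2

#: Canonical column order of the cohort file format.
COHORT_COLUMNS = ("patient_id", "psad", "pirads", "primary_score", "isup")


class CohortValidationError(ValueError):
    """Raised when a patient record or cohort file violates an invariant.

    ``errors`` lists one human-readable message per offending row.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class PatientRecord:
    """One subject: triage test results plus the biopsy reference outcome.

    Parameters
    ----------
    patient_id
        Opaque unique identifier.
    psad
        PSA density in ng/mL/cc, nonnegative.
    pirads
        mpMRI PI-RADS score in 1..5, or ``None`` when mpMRI was not
        performed / not scorable.
    primary_score
        PSMA-PET PRIMARY score in 1..5, or ``None`` when PET is missing.
    isup
        ISUP grade group in 0..5; 0 means negative biopsy.
    """

    patient_id: str
    psad: float
    pirads: Optional[int] = None
    primary_score: Optional[int] = None
    isup: Optional[int] = None

    def __post_init__(self) -> None:
        errs = []
        if not self.patient_id:
            errs.append("patient_id must be nonempty")
        if not (self.psad >= 0):
            errs.append(f"psad must be >= 0, got {self.psad}")
        for name in ("pirads", "primary_score"):
            v = getattr(self, name)
            if v is not None and v not in (1, 2, 3, 4, 5):
                errs.append(f"{name} must be in 1..5 or missing, got {v}")
        if self.isup is not None and self.isup not in (0, 1, 2, 3, 4, 5):
            errs.append(f"isup must be in 0..5, got {self.isup}")
        if errs:
            raise CohortValidationError(errs)


def is_cspca(record: PatientRecord) -> bool:
    """True iff the biopsy showed clinically significant cancer (ISUP >= 2)."""
    if record.isup is None:
        raise CohortValidationError(
            [f"patient {record.patient_id}: isup missing, csPCa status undefined"]
        )
    return record.isup >= CSPCA_ISUP_THRESHOLD


@dataclass(frozen=True)
class Cohort:
    """Ordered, id-unique collection of :class:`PatientRecord`."""

    records: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError([f"duplicate patient_id: {d}" for d in dupes])

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord]) -> "Cohort":
        return cls(tuple(records))

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def n_cspca(self) -> int:
        """Number of patients meeting the csPCa reference standard."""
        return sum(is_cspca(r) for r in self.records)

    def subset(self, indices: Sequence[int]) -> list[PatientRecord]:
        """Records at ``indices`` (with repeats), e.g. a bootstrap resample."""
        return [self.records[i] for i in indices]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the canonical column order; missing -> NA."""
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "psad": r.psad,
                    "pirads": r.pirads,
                    "primary_score": r.primary_score,
                    "isup": r.isup,
                }
                for r in self.records
            ],
            columns=list(COHORT_COLUMNS),
        )


@dataclass(frozen=True)
class UnitCostTable:
    """Per-procedure reimbursement costs in EUR.

    Defaults are institutional tariffs under the Italian National Health
    System: PSA assay 1.55, mpMRI 283.50, PSMA-PET 938.00, fusion biopsy
    809.40, pathology exam 81.80.  Internally every amount is converted
    to integer euro-cents so cohort totals are exact.
    """

    psa: float = 1.55
    mpmri: float = 283.5
    pet: float = 938.0
    biopsy: float = 809.4
    pathology: float = 81.8

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"unit cost {f.name} must be >= 0, got {v}")

    def cents(self, procedure: str) -> int:
        """Unit cost of ``procedure`` in integer euro-cents."""
        return round(getattr(self, procedure) * 100)

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitCostTable":
        """Load unit costs from a JSON or YAML mapping (keys as field names)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Cohort file I/O (delimited text; CSV by default, empty cell = missing)
# ---------------------------------------------------------------------------

def _parse_optional_int(value, name: str, row: int, errs: list[str]) -> Optional[int]:
    if pd.isna(value) or value == "":
        return None
    try:
        f = float(value)
        iv = int(f)
        if iv != f:
            raise ValueError
        return iv
    except (TypeError, ValueError):
        errs.append(f"row {row}: unparseable {name} value {value!r}")
        return None


def read_cohort(path: str | Path, *, delimiter: str = ",") -> Cohort:
    """Read and validate a cohort file.

    The file is delimited text with a header row and columns
    ``patient_id, psad, pirads, primary_score, isup``; an empty cell
    means missing.  Every offending row is reported (1-based data row
    numbers) in a single :class:`CohortValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError([f"missing column: {c}" for c in missing_cols])

    errs: list[str] = []
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_errs: list[str] = []
        pirads = _parse_optional_int(row.pirads, "pirads", i, row_errs)
        primary = _parse_optional_int(row.primary_score, "primary_score", i, row_errs)
        isup = _parse_optional_int(row.isup, "isup", i, row_errs)
        try:
            psad = float(row.psad)
        except (TypeError, ValueError):
            row_errs.append(f"row {i}: unparseable psad value {row.psad!r}")
            psad = float("nan")
        if not row_errs:
            try:
                records.append(
                    PatientRecord(
                        patient_id=str(row.patient_id),
                        psad=psad,
                        pirads=pirads,
                        primary_score=primary,
                        isup=isup,
                    )
                )
            except CohortValidationError as e:
                row_errs.extend(f"row {i}: {m}" for m in e.errors)
        errs.extend(row_errs)
    if errs:
        raise CohortValidationError(errs)
    cohort = Cohort.from_records(records)
    logger.info("read cohort %s: n=%d, csPCa=%d", path, cohort.n, cohort.n_cspca)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a cohort file that :func:`read_cohort` round-trips bit-exactly.

    Floats are written with ``repr`` so values survive the round trip;
    missing scores become empty cells.
    """
    path = Path(path)
    lines = [delimiter.join(COHORT_COLUMNS)]
    for r in cohort:
        cells = [
            r.patient_id,
            repr(r.psad),
            "" if r.pirads is None else str(r.pirads),
            "" if r.primary_score is None else str(r.primary_score),
            "" if r.isup is None else str(r.isup),
        ]
        lines.append(delimiter.join(cells))
    path.write_text("\n".join(lines) + "\n")
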