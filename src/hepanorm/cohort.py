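"""Per-patient measurement tables: data model, validation, CSV I/O.

The canonical interchange format is a UTF-8 comma-separated table with the
header ``patient_id,age,sex,roi_s3,roi_s4b,roi_s7,aorta,portal_vein``.
Concentrations are iodine in mg/ml, age in years.  Extra columns (e.g. HU
values exported alongside the iodine measurements) are tolerated and ignored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "Sex",
    "PatientRecord",
    "Cohort",
    "RowReject",
    "CohortValidationError",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "COLUMNS",
]

COLUMNS = ("patient_id", "age", "sex", "roi_s3", "roi_s4b", "roi_s7", "aorta", "portal_vein")

_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}

AGE_WINDOW = (0.0, 120.0)


class CohortFormatError(ValueError):
    """The input table is structurally unusable (e.g. a required column is missing)."""


class CohortValidationError(ValueError):
    """Cohort-level integrity violation (e.g. duplicate patient ids, strict mode)."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, raw: str) -> "Sex":
        key = str(raw).strip().lower()
        if key not in _SEX_ALIASES:
            raise ValueError(f"unrecognized sex code {raw!r}")
        return cls(_SEX_ALIASES[key])


@dataclass(frozen=True)
class PatientRecord:
    """One patient's raw ROI and vessel iodine measurements plus demographics.

    All concentrations are mg/ml.  Vessel concentrations must be strictly
    positive because they are used as divisors during blood normalization.
    """

    patient_id: str
    age: float
    sex: Sex
    roi_s3: float
    roi_s4b: float
    roi_s7: float
    aorta: float
    portal_vein: float

    def __post_init__(self) -> None:
        for name in ("age", "roi_s3", "roi_s4b", "roi_s7", "aorta", "portal_vein"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if not (AGE_WINDOW[0] <= self.age <= AGE_WINDOW[1]):
            raise ValueError(f"age {self.age} outside plausibility window {AGE_WINDOW}")
        for name in ("roi_s3", "roi_s4b", "roi_s7"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aorta <= 0 or self.portal_vein <= 0:
            raise ValueError("nonpositive vessel concentration")

    @property
    def rois(self) -> tuple[float, float, float]:
        return (self.roi_s3, self.roi_s4b, self.roi_s7)


@dataclass(frozen=True)
class RowReject:
    """A rejected input row and the reason it failed validation."""

    row_index: int
    patient_id: str
    reason: str


@dataclass
class Cohort:
    """An ordered collection of validated patient records."""

    records: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def subset(self, sex: Sex) -> "Cohort":
        return Cohort([r for r in self.records if r.sex is sex],
                      metadata={**self.metadata, "filter": f"sex={sex.value}"})

    def ages(self) -> list[float]:
        return [r.age for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex.value for r in self.records],
                "roi_s3": [r.roi_s3 for r in self.records],
                "roi_s4b": [r.roi_s4b for r in self.records],
                "roi_s7": [r.roi_s7 for r in self.records],
                "aorta": [r.aorta for r in self.records],
                "portal_vein": [r.portal_vein for r in self.records],
            }
        )


def _record_from_row(idx: int, row: pd.Series) -> PatientRecord:
    pid = str(row["patient_id"]).strip()
    if not pid or pid.lower() == "nan":
        raise ValueError("missing patient_id")
    try:
        sex = Sex.parse(row["sex"])
    except ValueError as e:
        raise ValueError(str(e)) from None
    numeric = {}
    for name in ("age", "roi_s3", "roi_s4b", "roi_s7", "aorta", "portal_vein"):
        try:
            numeric[name] = float(row[name])
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric value for {name}: {row[name]!r}") from None
    return PatientRecord(patient_id=pid, sex=sex, **numeric)


def cohort_from_frame(
    df: pd.DataFrame, *, strict: bool = False, source: str | None = None
) -> tuple[Cohort, list[RowReject]]:
    """Validate a raw table row by row.

    Every input row is either accepted into the cohort or accounted for in the
    returned reject list.  In strict mode any reject raises instead.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    rejects: list[RowReject] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            rec = _record_from_row(idx, row)
        except ValueError as e:
            rejects.append(RowReject(int(idx), pid, str(e)))
            continue
        if rec.patient_id in seen_ids:
            raise CohortValidationError(f"duplicate patient_id {rec.patient_id!r}")
        seen_ids.add(rec.patient_id)
        records.append(rec)

    if strict and rejects:
        detail = "; ".join(f"row {r.row_index} ({r.patient_id}): {r.reason}" for r in rejects)
        raise CohortValidationError(f"strict mode: {len(rejects)} row(s) rejected: {detail}")

    meta = {"n_input_rows": len(df), "n_rejected": len(rejects)}
    if source:
        meta["source"] = source
    return Cohort(records, metadata=meta), rejects


def read_cohort(path: str | Path, *, strict: bool = False) -> tuple[Cohort, list[RowReject]]:
    """Read and validate the canonical CSV layout.

    Returns the cohort together with the list of rejected rows; row order of
    the input file is preserved in the cohort.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str}, float_precision="round_trip")
    return cohort_from_frame(df, strict=strict, source=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical CSV layout; ``read_cohort`` round-trips it exactly.

    Floats are serialized with repr-level precision so no information is lost.
    """
    path = Path(path)
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
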