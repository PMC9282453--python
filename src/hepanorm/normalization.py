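"""Absolute and blood-normalized liver iodine concentrations.

Per patient, three liver ROI measurements are averaged into an absolute
concentration.  Because the contrast agent reaches the liver through the
portal vein (~75% of flow) and the hepatic artery (~25%), the per-patient
supply concentration is modelled as a weighted mix of the two vessels.
Dividing the absolute liver value by the patient's own supply concentration
and rescaling by the cohort-average supply concentration removes per-patient
circulatory variation while keeping mg/ml units.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "DEFAULT_WEIGHTS",
    "BloodReference",
    "NormalizedRecord",
    "absolute_liver_iodine",
    "mixed_blood_iodine",
    "blood_reference",
    "normalize_cohort",
    "write_normalized",
]

DEFAULT_WEIGHTS = (0.75, 0.25)
_WEIGHT_TOL = 1e-9


class ReferenceSource(str, enum.Enum):
    COMPUTED_FROM_COHORT = "computed_from_cohort"
    EXTERNALLY_SUPPLIED = "externally_supplied"


def _check_weights(weights: tuple[float, float]) -> tuple[float, float]:
    w_pv, w_a = float(weights[0]), float(weights[1])
    if w_pv < 0 or w_a < 0 or abs(w_pv + w_a - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"supply weights must be non-negative and sum to 1, got {weights}")
    return w_pv, w_a


def absolute_liver_iodine(roi_s3: float, roi_s4b: float, roi_s7: float) -> float:
    """Unweighted arithmetic mean of the three liver ROI concentrations (mg/ml)."""
    vals = (roi_s3, roi_s4b, roi_s7)
    if any(not math.isfinite(v) for v in vals):
        raise ValueError(f"ROI values must be finite, got {vals}")
    if any(v < 0 for v in vals):
        raise ValueError(f"ROI values must be >= 0, got {vals}")
    return (roi_s3 + roi_s4b + roi_s7) / 3.0


def mixed_blood_iodine(
    portal_vein: float, aorta: float, weights: tuple[float, float] = DEFAULT_WEIGHTS
) -> float:
    """Supply-weighted blood concentration ``w_pv*portal_vein + w_a*aorta`` (mg/ml)."""
    w_pv, w_a = _check_weights(weights)
    return w_pv * portal_vein + w_a * aorta


@dataclass(frozen=True)
class BloodReference:
    """Cohort-average vessel concentrations used as the normalization scale."""

    mean_portal_vein: float
    mean_aorta: float
    mean_mixed: float
    n_patients: int
    source: ReferenceSource = ReferenceSource.COMPUTED_FROM_COHORT

    def __post_init__(self) -> None:
        if self.mean_portal_vein <= 0 or self.mean_aorta <= 0 or self.mean_mixed <= 0:
            raise ValueError("blood reference means must be > 0")


def blood_reference(
    cohort: Cohort, weights: tuple[float, float] = DEFAULT_WEIGHTS
) -> BloodReference:
    """Per-vessel arithmetic means over all cohort patients.

    The mixed mean is derived from the vessel means by linearity, which is
    identical to averaging the per-patient mixed values.
    """
    if len(cohort) == 0:
        raise ValueError("cannot compute a blood reference from an empty cohort")
    w_pv, w_a = _check_weights(weights)
    pv = float(np.mean([r.portal_vein for r in cohort]))
    a = float(np.mean([r.aorta for r in cohort]))
    return BloodReference(
        mean_portal_vein=pv,
        mean_aorta=a,
        mean_mixed=w_pv * pv + w_a * a,
        n_patients=len(cohort),
        source=ReferenceSource.COMPUTED_FROM_COHORT,
    )


@dataclass(frozen=True)
class NormalizedRecord:
    """Per-patient derived concentrations, all mg/ml."""

    patient_id: str
    i_l_abs: float
    i_mixed_blood: float
    i_pv_n: float
    i_a_n: float
    i_mixed_n: float


def normalize_cohort(
    cohort: Cohort,
    reference: BloodReference | None = None,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> list[NormalizedRecord]:
    """Compute absolute and all three blood-normalized concentrations per patient.

    If no reference is given it is computed from this cohort (the default,
    self-calibrating convention); a supplied reference applies a fixed
    calibration, e.g. the published cohort averages, to new patients.
    Record order follows the cohort.
    """
    w_pv, w_a = _check_weights(weights)
    if reference is None:
        reference = blood_reference(cohort, weights)
    out: list[NormalizedRecord] = []
    for r in cohort:
        i_abs = absolute_liver_iodine(*r.rois)
        i_mixed = w_pv * r.portal_vein + w_a * r.aorta
        out.append(
            NormalizedRecord(
                patient_id=r.patient_id,
                i_l_abs=i_abs,
                i_mixed_blood=i_mixed,
                i_pv_n=i_abs / r.portal_vein * reference.mean_portal_vein,
                i_a_n=i_abs / r.aorta * reference.mean_aorta,
                i_mixed_n=i_abs / i_mixed * reference.mean_mixed,
            )
        )
    return out


def normalized_frame(records: Sequence[NormalizedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "i_l_abs": [r.i_l_abs for r in records],
            "i_mixed_blood": [r.i_mixed_blood for r in records],
            "i_pv_n": [r.i_pv_n for r in records],
            "i_a_n": [r.i_a_n for r in records],
            "i_mixed_n": [r.i_mixed_n for r in records],
        }
    )


def write_normalized(records: Sequence[NormalizedRecord], path: str | Path) -> None:
    """Emit the normalized output table at full precision."""
    normalized_frame(records).to_csv(path, index=False, float_format="%.17g")
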