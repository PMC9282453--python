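"""Physiological reference ranges: mean +/- two standard deviations.

Ranges are stratified by sex only where the sex comparison on the same
measure is significant; blood-normalized ranges additionally carry a per-year
age adjustment given by the fitted regression slope, anchored at the cohort's
reference age.
"""

from __future__ import annotations

import decimal
import enum
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .stats import TestResult

__all__ = [
    "Measure",
    "Stratum",
    "ReferenceRange",
    "reference_range",
    "range_from_moments",
    "stratification_policy",
    "age_adjusted_range",
    "round_half_up",
]


class Measure(str, enum.Enum):
    ABSOLUTE = "absolute"
    PV_NORMALIZED = "pv_normalized"
    AORTA_NORMALIZED = "aorta_normalized"
    MIXED_NORMALIZED = "mixed_normalized"


class Stratum(str, enum.Enum):
    ALL = "all"
    MALE = "male"
    FEMALE = "female"


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero, matching report conventions."""
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(x))).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ReferenceRange:
    """A mu +/- 2*sigma interval for one measure and stratum, in mg/ml.

    ``slope_per_year`` is 0 for measures that are not age-adjusted;
    ``reference_age`` is the age (years) at which the bounds apply unshifted.
    """

    measure: Measure
    stratum: Stratum
    mean: float
    sd: float
    lower: float
    upper: float
    slope_per_year: float = 0.0
    reference_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("bounds must bracket the mean")

    def rounded(self, decimals: int = 3, slope_decimals: int = 4) -> "ReferenceRange":
        return replace(
            self,
            mean=round_half_up(self.mean, decimals),
            sd=round_half_up(self.sd, decimals),
            lower=round_half_up(self.lower, decimals),
            upper=round_half_up(self.upper, decimals),
            slope_per_year=round_half_up(self.slope_per_year, slope_decimals),
        )


def range_from_moments(
    mean: float,
    sd: float,
    measure: Measure = Measure.MIXED_NORMALIZED,
    stratum: Stratum = Stratum.ALL,
    slope_per_year: float = 0.0,
    reference_age: Optional[float] = None,
) -> ReferenceRange:
    """Build a mu +/- 2*sigma range directly from summary moments."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return ReferenceRange(
        measure=measure,
        stratum=stratum,
        mean=mean,
        sd=sd,
        lower=mean - 2.0 * sd,
        upper=mean + 2.0 * sd,
        slope_per_year=slope_per_year,
        reference_age=reference_age,
    )


def reference_range(
    values: Sequence[float],
    measure: Measure,
    stratum: Stratum = Stratum.ALL,
    slope_per_year: float = 0.0,
    reference_age: Optional[float] = None,
) -> ReferenceRange:
    """Estimate the mu +/- 2*sigma range from per-patient values.

    The standard deviation is the sample (n-1) estimator; computation is at
    full precision, rounding is a report-time concern.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to estimate a range")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return range_from_moments(
        mean, sd, measure=measure, stratum=stratum,
        slope_per_year=slope_per_year, reference_age=reference_age,
    )


def stratification_policy(gender_test: TestResult) -> list[Stratum]:
    """Per-sex strata when the gender comparison is significant, pooled
    otherwise.  p exactly equal to alpha pools (strict inequality)."""
    if gender_test.p_value < gender_test.alpha:
        return [Stratum.MALE, Stratum.FEMALE]
    return [Stratum.ALL]


def age_adjusted_range(
    base: ReferenceRange, slope_per_year: float, age: float,
    observed_age_span: Optional[tuple[float, float]] = None,
) -> ReferenceRange:
    """Shift a range to a patient's age along the fitted regression line.

    Both bounds and the mean move by ``slope_per_year * (age - reference_age)``;
    the width never changes.  Ages outside the cohort's observed span trigger
    an extrapolation warning, not an error.
    """
    if base.reference_age is None:
        raise ValueError("base range has no reference_age set")
    if observed_age_span is not None and not (
        observed_age_span[0] <= age <= observed_age_span[1]
    ):
        warnings.warn(
            f"age {age} outside observed cohort span {observed_age_span}; "
            "range is extrapolated",
            UserWarning,
            stacklevel=2,
        )
    shift = slope_per_year * (age - base.reference_age)
    return replace(
        base,
        mean=base.mean + shift,
        lower=base.lower + shift,
        upper=base.upper + shift,
        slope_per_year=slope_per_year,
        reference_age=age,
    )
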