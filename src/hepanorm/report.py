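"""End-to-end analysis: cohort -> normalization -> tests -> reference ranges.

Produces a ``RunReport`` holding descriptive statistics per stratum, the full
test battery, and the reference-range table with per-year age adjustments for
the blood-normalized measures.  Report tables round concentrations to 3
decimals and slopes to 4; full-precision variants are kept alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort import Cohort, Sex
from .normalization import (
    DEFAULT_WEIGHTS,
    BloodReference,
    blood_reference,
    normalize_cohort,
    normalized_frame,
)
from .ranges import (
    Measure,
    ReferenceRange,
    Stratum,
    age_adjusted_range,
    reference_range,
    round_half_up,
    stratification_policy,
)
from .stats import TestResult, mann_whitney_gender, pearson_age, simple_linear_regression

__all__ = ["RunReport", "analyze_cohort", "write_report"]

CONC_DECIMALS = 3
SLOPE_DECIMALS = 4

_MEASURE_COLS = {
    Measure.ABSOLUTE: "i_l_abs",
    Measure.PV_NORMALIZED: "i_pv_n",
    Measure.AORTA_NORMALIZED: "i_a_n",
    Measure.MIXED_NORMALIZED: "i_mixed_n",
}
_ROI_COLS = ("roi_s3", "roi_s4b", "roi_s7")
_VESSEL_COLS = ("aorta", "portal_vein")


@dataclass
class RunReport:
    """Everything the analysis produces for one cohort."""

    cohort_summary: dict
    roi_stats: pd.DataFrame       # per-ROI mean/sd by stratum
    vessel_stats: pd.DataFrame    # per-vessel mean/sd by stratum
    measure_stats: pd.DataFrame   # per-measure mean/sd by stratum
    ranges: list[ReferenceRange]  # full precision
    gender_tests: dict[Measure, TestResult]
    pearson_tests: dict[Measure, TestResult]
    regressions: dict[Measure, TestResult]
    blood_ref: BloodReference
    normalized: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def ranges_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = []
        for rr in self.ranges:
            r = rr.rounded(CONC_DECIMALS, SLOPE_DECIMALS) if rounded else rr
            rows.append(
                {
                    "measure": r.measure.value,
                    "stratum": r.stratum.value,
                    "mean": r.mean,
                    "sd": r.sd,
                    "lower": r.lower,
                    "upper": r.upper,
                    "slope_per_year": r.slope_per_year,
                    "reference_age": r.reference_age,
                }
            )
        return pd.DataFrame(rows)

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for family, tests in (
            ("gender_mann_whitney", self.gender_tests),
            ("age_pearson", self.pearson_tests),
            ("age_regression", self.regressions),
        ):
            for measure, t in tests.items():
                eff = t.effect
                rows.append(
                    {
                        "family": family,
                        "measure": measure.value,
                        "statistic": t.statistic,
                        "p_value": t.p_value,
                        "significant": t.significant,
                        "n": "/".join(str(k) for k in t.n),
                        "r": eff.r if eff else None,
                        "r_squared": eff.r_squared if eff else None,
                        "slope": eff.slope if eff else None,
                        "intercept": eff.intercept if eff else None,
                    }
                )
        return pd.DataFrame(rows)


def _stratum_frames(df: pd.DataFrame) -> dict[Stratum, pd.DataFrame]:
    return {
        Stratum.ALL: df,
        Stratum.MALE: df[df["sex"] == "male"],
        Stratum.FEMALE: df[df["sex"] == "female"],
    }


def _mean_sd_table(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for col in cols:
        row: dict = {"variable": col}
        for stratum, sub in _stratum_frames(df).items():
            vals = sub[col].to_numpy(dtype=float)
            row[f"{stratum.value}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{stratum.value}_sd"] = (
                float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: Cohort,
    alpha: float = 0.05,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    reference_age: Optional[float] = None,
    adjust_absolute_for_age: bool = False,
) -> RunReport:
    """Run the whole pipeline on a validated cohort.

    ``reference_age`` defaults to the cohort mean age rounded to the nearest
    year.  Age adjustment is attached to the blood-normalized measures only,
    unless ``adjust_absolute_for_age`` forces it everywhere.
    """
    if len(cohort) < 2:
        raise ValueError("analysis requires at least 2 patients")
    raw = cohort.to_frame()
    ages = raw["age"].to_numpy(dtype=float)
    sexes = [r.sex for r in cohort]
    n_female = sum(1 for s in sexes if s is Sex.FEMALE)

    ref = blood_reference(cohort, weights)
    normalized = normalize_cohort(cohort, ref, weights)
    norm_df = normalized_frame(normalized)
    merged = raw.merge(norm_df, on="patient_id")

    if reference_age is None:
        reference_age = round_half_up(float(ages.mean()), 0)

    gender_tests: dict[Measure, TestResult] = {}
    pearson_tests: dict[Measure, TestResult] = {}
    regressions: dict[Measure, TestResult] = {}
    for measure, col in _MEASURE_COLS.items():
        vals = merged[col].to_numpy(dtype=float)
        gender_tests[measure] = mann_whitney_gender(vals, sexes, alpha=alpha)
        pearson_tests[measure] = pearson_age(vals, ages, alpha=alpha)
        regressions[measure] = simple_linear_regression(vals, ages)

    strata_frames = _stratum_frames(merged)
    ranges: list[ReferenceRange] = []
    for measure, col in _MEASURE_COLS.items():
        age_adjusted = adjust_absolute_for_age or measure is not Measure.ABSOLUTE
        slope = regressions[measure].statistic if age_adjusted else 0.0
        for stratum in stratification_policy(gender_tests[measure]):
            vals = strata_frames[stratum][col].to_numpy(dtype=float)
            ranges.append(
                reference_range(
                    vals,
                    measure=measure,
                    stratum=stratum,
                    slope_per_year=slope,
                    reference_age=reference_age,
                )
            )

    summary = {
        "n": len(cohort),
        "n_male": len(cohort) - n_female,
        "n_female": n_female,
        "age_mean": float(ages.mean()),
        "age_min": float(ages.min()),
        "age_max": float(ages.max()),
        "reference_age": reference_age,
        "alpha": alpha,
        "supply_weights": list(weights),
    }
    return RunReport(
        cohort_summary=summary,
        roi_stats=_mean_sd_table(merged, _ROI_COLS),
        vessel_stats=_mean_sd_table(merged, _VESSEL_COLS),
        measure_stats=_mean_sd_table(merged, tuple(_MEASURE_COLS.values())),
        ranges=ranges,
        gender_tests=gender_tests,
        pearson_tests=pearson_tests,
        regressions=regressions,
        blood_ref=ref,
        normalized=norm_df,
        provenance={
            "software": f"hepanorm {__version__}",
            **{k: v for k, v in cohort.metadata.items()},
        },
    )


def _round_df(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda x: round_half_up(x, decimals) if pd.notna(x) else x
            )
    return out


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write all report artifacts (CSV tables + JSON summary) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _round_df(report.roi_stats, CONC_DECIMALS).to_csv(out / "roi_stats.csv", index=False)
    _round_df(report.vessel_stats, CONC_DECIMALS).to_csv(out / "vessel_stats.csv", index=False)
    _round_df(report.measure_stats, CONC_DECIMALS).to_csv(out / "measure_stats.csv", index=False)
    report.ranges_frame(rounded=True).to_csv(out / "ranges.csv", index=False)
    report.ranges_frame(rounded=False).to_csv(
        out / "ranges_full.csv", index=False, float_format="%.17g"
    )
    report.tests_frame().to_csv(out / "tests.csv", index=False, float_format="%.17g")
    report.normalized.to_csv(out / "normalized.csv", index=False, float_format="%.17g")
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "cohort": report.cohort_summary,
                "blood_reference": {
                    "mean_portal_vein": report.blood_ref.mean_portal_vein,
                    "mean_aorta": report.blood_ref.mean_aorta,
                    "mean_mixed": report.blood_ref.mean_mixed,
                    "n_patients": report.blood_ref.n_patients,
                    "source": report.blood_ref.source.value,
                },
                "provenance": report.provenance,
            },
            fh,
            indent=2,
        )
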