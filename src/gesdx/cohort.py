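"""Cohort file reading/writing and protocol exclusion rules.

Cohort files are comma-separated UTF-8 text with a header row and one row per
subject: ``id, status, h1, h2, h3, h4, age, sex`` with optional
``meal_fraction`` and ``meal_minutes`` columns.  ``status`` is 1 for
gastroparesis, 0 otherwise; ``sex`` is coded F/M.  Subjects who consumed an
unusually small fraction of the test meal (< 20%) or took unusually long
(> 30 minutes) have unreliable retention measurements and are excluded before
any analysis.
"""

from __future__ import annotations

import pandas as pd

from .roc import GroupedMarkers, InvalidInputError
from .simulate import MARKERS

REQUIRED_COLUMNS = ("id", "status", "h1", "h2", "h3", "h4", "age", "sex")
OPTIONAL_COLUMNS = ("meal_fraction", "meal_minutes")


class SchemaError(ValueError):
    """A cohort file does not match the expected column schema."""


def read_cohort(path) -> pd.DataFrame:
    """Read and type-check a cohort CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing column(s): {missing}")
    numeric = ["status", *MARKERS, "age"] + [
        c for c in OPTIONAL_COLUMNS if c in df.columns
    ]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise SchemaError(
                f"unparseable value in column {col!r} at line {line}"
            )
        df[col] = parsed
    if not df["status"].isin([0, 1]).all():
        raise SchemaError("status must be 0/1")
    if not df["sex"].isin(["F", "M"]).all():
        raise SchemaError("sex must be coded F/M")
    return df


def write_cohort(cohort: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    cohort.to_csv(path, index=False, float_format=float_format)


def apply_exclusions(
    cohort: pd.DataFrame,
    min_meal_fraction: float = 0.20,
    max_meal_minutes: float = 30.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop subjects violating the meal-consumption protocol.

    Returns the filtered cohort and a log of removals (one entry per dropped
    subject, with the reason).  A no-op when the meal columns are absent.
    The filter is idempotent.
    """
    log: list[dict] = []
    mask = pd.Series(False, index=cohort.index)
    if "meal_fraction" in cohort.columns:
        bad = cohort["meal_fraction"] < min_meal_fraction
        for _, row in cohort[bad].iterrows():
            log.append(
                {
                    "id": row["id"],
                    "reason": f"meal_fraction {row['meal_fraction']:.2f} "
                    f"< {min_meal_fraction}",
                }
            )
        mask |= bad
    if "meal_minutes" in cohort.columns:
        bad = (cohort["meal_minutes"] > max_meal_minutes) & ~mask
        for _, row in cohort[bad].iterrows():
            log.append(
                {
                    "id": row["id"],
                    "reason": f"meal_minutes {row['meal_minutes']:.1f} "
                    f"> {max_meal_minutes}",
                }
            )
        mask |= cohort["meal_minutes"] > max_meal_minutes
    return cohort[~mask].reset_index(drop=True), log


def to_grouped_markers(cohort: pd.DataFrame, markers=MARKERS) -> GroupedMarkers:
    """Split a cohort table into diseased/control marker matrices."""
    markers = tuple(markers)
    for m in markers:
        if m not in cohort.columns:
            raise SchemaError(f"marker column {m!r} not in cohort")
    diseased = cohort.loc[cohort["status"] == 1, list(markers)].to_numpy(float)
    control = cohort.loc[cohort["status"] == 0, list(markers)].to_numpy(float)
    if len(diseased) < 2 or len(control) < 2:
        raise InvalidInputError("need at least 2 subjects per group")
    return GroupedMarkers(diseased, control, markers)


def feature_frame(cohort: pd.DataFrame, markers=MARKERS, covariates=("age", "sex")):
    """Tree feature matrix: markers plus covariates, sex as a 0/1 indicator
    (female = 1; two levels only, split as numeric)."""
    cols = {m: cohort[m].to_numpy(float) for m in markers}
    if "age" in covariates:
        cols["age"] = cohort["age"].to_numpy(float)
    if "sex" in covariates:
        cols["sex"] = (cohort["sex"] == "F").to_numpy(float)
    return pd.DataFrame(cols), cohort["status"].to_numpy(int)
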