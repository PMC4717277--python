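"""Long-format longitudinal cohort I/O, validation, derived variables,
exclusion filtering, blood-pressure-treatment adjustment, and attrition
summaries.

A cohort is a long-format table with one row per subject per attended exam.
Units follow mid-20th-century US clinical-exam conventions throughout:
blood pressures in mm Hg, blood glucose in mg/dL, height in inches, weight
in pounds, BMI in kg/m^2 computed with the imperial constant
(703 * weight[lb] / height[in]^2).  Dates are fractional calendar years and
ages are plain date differences in years.

Expected CSV header (empty cell = missing)::

    subject_id, sex, birth_year, death_year, followup_complete,
    exam_index, exam_year, sbp, dbp, glucose, height_in, weight_lb,
    bmi, bp_treated
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The six-variable physiological panel measured consistently across exams.
PANEL = ["sbp", "dbp", "glucose", "height_in", "weight_lb", "bmi"]

#: Panel extended with the derived pulse-pressure variable (univariate
#: analyses only; linearly dependent on sbp and dbp).
PANEL_WITH_PP = PANEL + ["pulse_pressure"]

STATIC_COLUMNS = ["subject_id", "sex", "birth_year", "death_year", "followup_complete"]
EXAM_COLUMNS = ["exam_index", "exam_year"] + PANEL + ["bp_treated"]
REQUIRED_COLUMNS = STATIC_COLUMNS + EXAM_COLUMNS

#: Imperial BMI constant: kg m^-2 per (lb / in^2).
BMI_IMPERIAL_CONSTANT = 703.0

_BOOL_MAP = {
    "True": True, "False": False, "true": True, "false": False,
    "1": True, "0": False, 1: True, 0: False, 1.0: True, 0.0: False,
    True: True, False: False,
}


class CohortValidationError(ValueError):
    """Structural problem with an input cohort table (missing columns,
    duplicated subject-exam rows, ...)."""


@dataclass
class LongitudinalCohort:
    """A collection of subjects sharing an exam-wave calendar.

    Parameters
    ----------
    data:
        Long-format table, one row per subject per attended exam, with the
        columns listed in :data:`REQUIRED_COLUMNS` (plus any derived ones).
    exam_calendar:
        Series mapping exam_index -> shared wave date (calendar year).
    variable_panel:
        Ordered names of the physiological variables used in analyses.
    rejects:
        Rows that failed row-level validation on read, with a ``reason``
        column.  Never silently dropped.
    """

    data: pd.DataFrame
    exam_calendar: pd.Series
    variable_panel: list[str] = field(default_factory=lambda: list(PANEL))
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def subject_table(self) -> pd.DataFrame:
        """One row per subject with the static attributes."""
        return (
            self.data[STATIC_COLUMNS]
            .drop_duplicates("subject_id")
            .set_index("subject_id")
        )

    def exam_rows(self, exam_index: int) -> pd.DataFrame:
        return self.data[self.data["exam_index"] == exam_index]

    def copy(self) -> "LongitudinalCohort":
        return replace(
            self,
            data=self.data.copy(),
            exam_calendar=self.exam_calendar.copy(),
            variable_panel=list(self.variable_panel),
            rejects=self.rejects.copy(),
        )

    def subset(self, subject_ids) -> "LongitudinalCohort":
        keep = self.data["subject_id"].isin(set(subject_ids))
        return replace(self, data=self.data[keep].reset_index(drop=True))


def _coerce_bool(series: pd.Series) -> pd.Series:
    out = series.map(lambda v: _BOOL_MAP.get(v, pd.NA))
    return out.astype("boolean")


def _row_level_checks(df: pd.DataFrame) -> pd.Series:
    """Return a reason string per invalid row, '' where valid."""
    reason = pd.Series("", index=df.index, dtype=object)

    bad_year = df["exam_year"].isna() | df["exam_index"].isna()
    reason[bad_year & (reason == "")] = "missing exam_index or exam_year"

    both_bp = df["sbp"].notna() & df["dbp"].notna()
    inverted = both_bp & (df["sbp"] <= df["dbp"])
    reason[inverted & (reason == "")] = "sbp not greater than dbp"

    for var in PANEL:
        nonpos = df[var].notna() & (df[var] <= 0)
        reason[nonpos & (reason == "")] = f"non-positive {var}"

    after_death = df["death_year"].notna() & (df["exam_year"] > df["death_year"])
    reason[after_death & (reason == "")] = "exam after death_date"
    return reason


def read_cohort(source, variable_panel: list[str] | None = None) -> LongitudinalCohort:
    """Read and validate a long-format cohort table.

    ``source`` may be a CSV path or an already-loaded DataFrame.  Malformed
    rows are collected into ``cohort.rejects`` with a reason, never silently
    dropped; structural problems raise :class:`CohortValidationError`.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, dtype={"subject_id": str})
    else:
        df = source.copy()
        df["subject_id"] = df["subject_id"].astype(str)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {', '.join(missing)}")

    for col in ("followup_complete", "bp_treated"):
        df[col] = _coerce_bool(df[col])
    for col in ["birth_year", "death_year", "exam_year"] + PANEL:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["exam_index"] = pd.to_numeric(df["exam_index"], errors="coerce").astype("Int64")

    dup = df.duplicated(subset=["subject_id", "exam_index"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "exam_index"]].drop_duplicates()
        raise CohortValidationError(
            f"duplicate subject-exam pair(s): {pairs.to_records(index=False).tolist()}"
        )

    reason = _row_level_checks(df)
    rejects = df[reason != ""].assign(reason=reason[reason != ""])
    clean = df[reason == ""].reset_index(drop=True)
    clean = clean.sort_values(["subject_id", "exam_index"]).reset_index(drop=True)

    # Shared wave date per exam index: median of the per-subject exam dates.
    calendar = clean.groupby("exam_index")["exam_year"].median()
    calendar.name = "exam_year"

    panel = list(variable_panel) if variable_panel is not None else list(PANEL)
    return LongitudinalCohort(
        data=clean,
        exam_calendar=calendar,
        variable_panel=panel,
        rejects=rejects.reset_index(drop=True),
    )


def write_cohort(cohort: LongitudinalCohort, path) -> Path:
    """Write the cohort to CSV; read/write round-trips are lossless for
    all fields including missingness (empty cell = missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = cohort.data.copy()
    cols = [c for c in REQUIRED_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False)
    return path


def derive_variables(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Fill the derived variables: pulse pressure and (where absent) BMI.

    pulse_pressure = sbp - dbp (mm Hg).  Missing BMI values are computed
    from weight and height with the imperial constant; BMI values already
    present are never overwritten, so the operation is idempotent.  Missing
    inputs propagate as missing.
    """
    out = cohort.copy()
    df = out.data
    df["pulse_pressure"] = df["sbp"] - df["dbp"]
    computed = BMI_IMPERIAL_CONSTANT * df["weight_lb"] / df["height_in"] ** 2
    df["bmi"] = df["bmi"].where(df["bmi"].notna(), computed)
    return out


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionCriteria:
    """Cohort-construction rules, applied in a fixed order so each excluded
    subject has exactly one primary reason:

    1. eligibility: age at the first exam inside [age_min, age_max];
    2. follow-up: exclude subjects lacking both a death date and any panel
       data at the final exam;
    3. completeness: exclude subjects missing any required variable at the
       reference exam;
    4. outlier: exclude subjects whose reference-exam value of any panel
       variable lies more than ``outlier_z`` sample standard deviations
       from the mean.
    """

    age_min: float = 28.0
    age_max: float = 38.0
    required_exam: int = 1
    required_vars: tuple[str, ...] = tuple(PANEL)
    final_exam: int | None = None  # default: last exam in the calendar
    outlier_z: float = 8.0
    outlier_action: str = "exclude"  # or "flag"


@dataclass
class ExclusionReport:
    """Attrition bookkeeping for :func:`apply_exclusions`.

    Satisfies n_retained = n_eligible - n_lost_followup -
    n_insufficient_data - n_outlier (checked at construction).
    """

    n_input: int
    n_eligible: int
    n_lost_followup: int
    n_insufficient_data: int
    n_outlier: int
    n_retained: int
    reasons: pd.DataFrame  # subject_id, reason
    outlier_flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        expected = (
            self.n_eligible
            - self.n_lost_followup
            - self.n_insufficient_data
            - self.n_outlier
        )
        if self.n_retained != expected:
            raise ValueError(
                f"exclusion arithmetic violated: retained {self.n_retained} != "
                f"{self.n_eligible} - {self.n_lost_followup} - "
                f"{self.n_insufficient_data} - {self.n_outlier}"
            )

    def counts(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "n_lost_followup": self.n_lost_followup,
            "n_insufficient_data": self.n_insufficient_data,
            "n_outlier": self.n_outlier,
            "n_retained": self.n_retained,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.counts(), indent=2) + "\n")

    def to_csv(self, path) -> None:
        self.reasons.to_csv(path, index=False)


def apply_exclusions(
    cohort: LongitudinalCohort,
    criteria: ExclusionCriteria | None = None,
) -> tuple[LongitudinalCohort, ExclusionReport]:
    """Apply the cohort-construction exclusions in their fixed order and
    return the retained cohort plus an :class:`ExclusionReport`.

    With no explicit criteria, completeness is judged on the cohort's own
    variable panel.
    """
    crit = criteria or ExclusionCriteria(required_vars=tuple(cohort.variable_panel))
    subjects = cohort.subject_table()
    n_input = len(subjects)
    final_exam = crit.final_exam or int(cohort.exam_calendar.index.max())
    exam1_year = float(cohort.exam_calendar.get(crit.required_exam, np.nan))

    reasons: list[tuple[str, str]] = []

    # 1. eligibility: age window at the reference exam
    exam1 = cohort.exam_rows(crit.required_exam).set_index("subject_id")
    age1 = exam1_year - subjects["birth_year"]
    # prefer the subject's own exam-1 date when attended
    own = exam1["exam_year"].reindex(subjects.index)
    age1 = own.fillna(exam1_year) - subjects["birth_year"]
    eligible = (age1 >= crit.age_min) & (age1 <= crit.age_max)
    for sid in subjects.index[~eligible]:
        reasons.append((sid, "ineligible_age"))
    pool = subjects.index[eligible]

    # 2. follow-up: no death date and no panel data at the final exam
    final_rows = cohort.exam_rows(final_exam)
    has_final = set(
        final_rows.loc[final_rows[list(crit.required_vars)].notna().any(axis=1),
                       "subject_id"]
    )
    has_death = set(subjects.index[subjects["death_year"].notna()])
    lost = [sid for sid in pool if sid not in has_death and sid not in has_final]
    reasons += [(sid, "lost_followup") for sid in lost]
    pool = pool.difference(lost)

    # 3. completeness at the reference exam
    complete = set(
        exam1.index[exam1[list(crit.required_vars)].notna().all(axis=1)]
    )
    insufficient = [sid for sid in pool if sid not in complete]
    reasons += [(sid, "insufficient_data") for sid in insufficient]
    pool = pool.difference(insufficient)

    # 4. outlier screen at the reference exam, among survivors of 1-3
    sub1 = exam1.loc[exam1.index.intersection(pool), list(crit.required_vars)]
    z = (sub1 - sub1.mean()) / sub1.std(ddof=1)
    flagged_mask = z.abs().gt(crit.outlier_z).any(axis=1)
    flags = pd.DataFrame(
        {
            "subject_id": sub1.index[flagged_mask],
            "max_abs_z": z.abs().max(axis=1)[flagged_mask].values,
        }
    )
    outliers = list(sub1.index[flagged_mask]) if crit.outlier_action == "exclude" else []
    reasons += [(sid, "outlier") for sid in outliers]
    pool = pool.difference(outliers)

    if len(pool) == 0:
        raise ValueError("no subjects retained after exclusions")

    report = ExclusionReport(
        n_input=n_input,
        n_eligible=int(eligible.sum()),
        n_lost_followup=len(lost),
        n_insufficient_data=len(insufficient),
        n_outlier=len(outliers),
        n_retained=len(pool),
        reasons=pd.DataFrame(reasons, columns=["subject_id", "reason"]),
        outlier_flags=flags,
    )
    return cohort.subset(pool), report


# ---------------------------------------------------------------------------
# Blood-pressure-treatment adjustment
# ---------------------------------------------------------------------------

def adjust_bp_treatment(
    cohort: LongitudinalCohort,
    delta_sbp: float,
    delta_dbp: float,
    scope: str = "treated_only",
) -> LongitudinalCohort:
    """Shift blood pressures by the average treatment effect to approximate
    untreated values.

    ``scope='treated_only'`` shifts only rows with bp_treated True (the
    default interpretation); ``scope='all'`` shifts every row.  The original
    values are kept in ``sbp_raw``/``dbp_raw`` so the adjustment is
    invertible via :func:`invert_bp_adjustment`.
    """
    if not (np.isfinite(delta_sbp) and np.isfinite(delta_dbp)):
        raise ValueError("treatment deltas must be finite")
    if scope not in ("treated_only", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    out = cohort.copy()
    df = out.data
    if "sbp_raw" not in df.columns:
        df["sbp_raw"] = df["sbp"]
        df["dbp_raw"] = df["dbp"]
    if scope == "all":
        mask = pd.Series(True, index=df.index)
    else:
        mask = df["bp_treated"].fillna(False).astype(bool)
    df.loc[mask, "sbp"] = df.loc[mask, "sbp"] + delta_sbp
    df.loc[mask, "dbp"] = df.loc[mask, "dbp"] + delta_dbp
    return out


def invert_bp_adjustment(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Restore the pre-adjustment blood pressures saved by
    :func:`adjust_bp_treatment`."""
    out = cohort.copy()
    df = out.data
    if "sbp_raw" not in df.columns:
        warnings.warn("cohort carries no bp adjustment to invert")
        return out
    df["sbp"] = df["sbp_raw"]
    df["dbp"] = df["dbp_raw"]
    out.data = df.drop(columns=["sbp_raw", "dbp_raw"])
    return out


# ---------------------------------------------------------------------------
# Attrition summary
# ---------------------------------------------------------------------------

def summarize_cohort(cohort: LongitudinalCohort) -> pd.DataFrame:
    """Per-exam demographics of the surviving subcohort.

    A subject is counted as living at exam e when their death date is after
    the wave date of exam e (or no death is recorded).  Living counts are
    non-increasing across exams by construction.
    """
    subjects = cohort.subject_table()
    rows = []
    for exam_index, wave_year in cohort.exam_calendar.sort_index().items():
        alive = subjects["death_year"].isna() | (subjects["death_year"] > wave_year)
        living = subjects[alive]
        ages = wave_year - living["birth_year"]
        n = len(living)
        n_male = int((living["sex"] == "male").sum())
        n_female = int((living["sex"] == "female").sum())
        rows.append(
            {
                "exam_index": exam_index,
                "exam_year": wave_year,
                "n_living": n,
                "mean_age": ages.mean(),
                "sd_age": ages.std(ddof=1),
                "n_male": n_male,
                "n_female": n_female,
                "pct_male": 100.0 * n_male / n if n else np.nan,
                "pct_female": 100.0 * n_female / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("exam_index")
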