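"""Correlation and regression machinery linking physiology to survival.

Survival is measured in days from a focal exam to death among the subjects
alive at that exam (the pipeline requires known death dates; right-censored
subjects are excluded upstream).  Composite risk scores are ordinary
least-squares fits of survival on a physiological panel; predictivity is
reported as Pearson r^2.  Plain linear models are used throughout — no
nonlinear or regularized variants — as a deliberate guard against
overfitting, and out-of-sample behaviour is checked by seeded k-fold
cross-validation with the r^2 computed on pooled out-of-fold predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

from .cohort_io import LongitudinalCohort, PANEL

DAYS_PER_YEAR = 365.25


class CollinearPanelError(ValueError):
    """The design matrix is rank-deficient; names the dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "collinear variable panel; linearly dependent set: "
            + ", ".join(self.columns)
        )


@dataclass
class CorrStats:
    """A correlation measurement: signed Pearson r, r^2, two-sided p, n.

    Degenerate inputs (constant feature or prediction) yield NaN statistics
    with the reason recorded in ``note`` rather than an exception.
    """

    r: float
    r2: float
    p: float
    n: int
    note: str | None = None

    @property
    def defined(self) -> bool:
        return self.note is None


@dataclass
class RiskModel:
    """Linear composite risk score over a named variable panel.

    Weights are in days of survival per variable unit; the intercept in
    days.  ``stderr`` holds the OLS standard errors (same order as
    ``panel``, intercept last) for parameter-recovery checks.
    """

    panel: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    fit_exam: int | None = None
    n_fit: int = 0
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.panel):
            raise ValueError("one weight per panel variable required")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("weights and intercept must be finite")

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.panel)
        return X @ self.weights + self.intercept

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "fit_exam": self.fit_exam,
            "n_fit": int(self.n_fit),
        }


def _as_matrix(X, panel=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if panel is not None:
            missing = [c for c in panel if c not in X.columns]
            if missing:
                raise ValueError(f"feature matrix lacks panel column(s): {missing}")
            X = X[list(panel)]
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if panel is not None and X.shape[1] != len(panel):
        raise ValueError("feature matrix width does not match model panel")
    return X


# ---------------------------------------------------------------------------
# Survival extraction
# ---------------------------------------------------------------------------

def survival_after(
    cohort: LongitudinalCohort,
    focal_exam: int,
    origin: str = "focal",
) -> pd.Series:
    """Days of survival after the focal exam, per subject alive then.

    Subjects dead at or before the focal wave date, or lacking a death
    date, are absent from the output.  ``origin='focal'`` (default)
    measures from the focal wave date; ``origin='first'`` measures from the
    first exam's date while still restricting to survivors at the focal
    exam.  Durations are rounded to the nearest whole day (365.25
    days/year convention).
    """
    calendar = cohort.exam_calendar
    if focal_exam not in calendar.index:
        raise ValueError(f"focal exam {focal_exam} not in the exam calendar")
    focal_year = float(calendar.loc[focal_exam])
    origin_year = focal_year if origin == "focal" else float(calendar.iloc[0])

    subjects = cohort.subject_table()
    alive = subjects["death_year"].notna() & (subjects["death_year"] > focal_year)
    days = np.round(
        (subjects.loc[alive, "death_year"] - origin_year) * DAYS_PER_YEAR
    ).astype(int)
    if len(days) == 0:
        raise ValueError(f"no survivors with known death dates at exam {focal_exam}")
    days.name = "survival_days"
    return days


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def univariate_r2(feature, survival) -> CorrStats:
    """Pearson correlation of one feature with survival, with the two-sided
    p-value from the standard t transform."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(survival, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return CorrStats(np.nan, np.nan, np.nan, n, note="fewer than 3 observations")
    if np.ptp(x) == 0:
        return CorrStats(np.nan, np.nan, np.nan, n, note="constant feature")
    if np.ptp(y) == 0:
        return CorrStats(np.nan, np.nan, np.nan, n, note="constant survival")
    r, p = stats.pearsonr(x, y)
    return CorrStats(r=float(r), r2=float(r) ** 2, p=float(p), n=n)


def partial_correlation(feature, survival, covariates) -> float:
    """Correlation of feature and survival after projecting both onto the
    covariates (residual correlation).

    An empty covariate set reduces to the plain Pearson r.  Rank-deficient
    covariates — including a covariate collinear with the feature — raise
    :class:`CollinearPanelError` naming the offending columns.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(survival, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        Z = covariates.to_numpy(dtype=float)
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z.reshape(-1, 1) if Z.size else Z.reshape(len(x), 0)
        names = [f"z{i}" for i in range(Z.shape[1])]
    if Z.shape[1] == 0:
        return float(univariate_r2(x, y).r)
    if len(x) <= Z.shape[1] + 2:
        raise ValueError("need n > number of covariates + 2")

    design = np.column_stack([np.ones(len(x)), Z])
    _check_rank(design, ["intercept"] + names)
    _check_rank(np.column_stack([design, x]), ["intercept"] + names + ["feature"])

    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(stats.pearsonr(rx, ry)[0])


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise CollinearPanelError naming the dependent columns if the design
    matrix is rank-deficient (columns scaled to unit norm first)."""
    norms = np.linalg.norm(design, axis=0)
    norms[norms == 0] = 1.0
    scaled = design / norms
    rank = np.linalg.matrix_rank(scaled)
    if rank < design.shape[1]:
        # smallest right-singular vector exposes the dependency
        _, _, vt = np.linalg.svd(scaled)
        null = vt[-1]
        involved = [names[i] for i in np.where(np.abs(null) > 1e-8)[0]]
        raise CollinearPanelError(involved)


# ---------------------------------------------------------------------------
# Composite linear risk scores
# ---------------------------------------------------------------------------

def fit_composite(features, survival, fit_exam: int | None = None) -> RiskModel:
    """Ordinary least-squares composite risk score.

    ``features`` is a DataFrame over the variable panel (pulse pressure
    must not be included alongside sbp and dbp: the panel is checked for
    exact collinearity and the dependent set is named in the error).
    """
    if isinstance(features, pd.DataFrame):
        panel = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        panel = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(survival, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} subjects to fit {p} weights")

    design = sm.add_constant(X, prepend=False)
    _check_rank(design, list(panel) + ["intercept"])
    fit = sm.OLS(y, design).fit()
    return RiskModel(
        panel=panel,
        weights=fit.params[:-1],
        intercept=float(fit.params[-1]),
        fit_exam=fit_exam,
        n_fit=n,
        stderr=np.asarray(fit.bse),
    )


def evaluate_model(model: RiskModel, features, survival) -> CorrStats:
    """Pearson r^2 between the model's predicted and actual survival."""
    pred = model.predict(features)
    y = np.asarray(survival, dtype=float)
    res = univariate_r2(pred, y)
    if res.note == "constant feature":
        res.note = "constant prediction"
    return res


def crossval_r2(features, survival, k_folds: int = 5, seed: int = 0) -> CorrStats:
    """Out-of-sample r^2 by seeded k-fold cross-validation.

    Subjects are randomly partitioned into ``k_folds`` folds; each fold is
    predicted by a composite fitted on the remaining folds; the r^2 is
    computed once on the pooled out-of-fold predictions.
    """
    X = _as_matrix(features)
    y = np.asarray(survival, dtype=float)
    n, p = X.shape
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n < 2 * k_folds:
        raise ValueError("need at least 2 subjects per fold")

    pred = np.empty(n)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        if len(train) < p + 2:
            raise ValueError("a training fold is too small for the panel")
        design = np.column_stack([X[train], np.ones(len(train))])
        coef = np.linalg.lstsq(design, y[train], rcond=None)[0]
        pred[test] = np.column_stack([X[test], np.ones(len(test))]) @ coef
    res = univariate_r2(pred, y)
    if res.note == "constant feature":
        res.note = "constant prediction"
    return res


# ---------------------------------------------------------------------------
# Focal-exam sweeps
# ---------------------------------------------------------------------------

def _complete_cases(cohort: LongitudinalCohort, exam: int, panel, stratum: str):
    rows = cohort.exam_rows(exam)
    if stratum != "all":
        rows = rows[rows["sex"] == stratum]
    rows = rows.dropna(subset=list(panel))
    return rows.set_index("subject_id")


def focal_sweep(
    cohort: LongitudinalCohort,
    mode: str = "refit",
    source_exam: int | None = None,
    panel: list[str] | None = None,
    stratum: str = "all",
    min_n: int | None = None,
    model: RiskModel | None = None,
) -> pd.DataFrame:
    """Composite predictivity across focal exams.

    Modes: ``refit`` re-fits the composite at every focal exam (an upper
    bound on linearly predictable survival variance); ``fixed`` fits once
    at ``source_exam`` and carries those weights forward; ``external``
    evaluates a supplied :class:`RiskModel` (the hook for externally
    published linear scores).  Survivors at each exam are complete cases on
    the panel at that exam; survival is measured from the focal exam date.

    Returns a tidy trace: focal_exam, exam_year, n, r, r2, p, mode,
    sex_stratum.  The trace ends with a warning once fewer than ``min_n``
    usable subjects remain.
    """
    panel = list(panel) if panel is not None else list(cohort.variable_panel)
    if min_n is None:
        min_n = max(25, len(panel) + 3)

    if mode == "fixed":
        if source_exam is None:
            raise ValueError("fixed mode requires source_exam")
        src = _complete_cases(cohort, source_exam, panel, stratum)
        surv = survival_after(cohort, source_exam)
        ids = src.index.intersection(surv.index)
        model = fit_composite(src.loc[ids, panel], surv.loc[ids], fit_exam=source_exam)
    elif mode == "external":
        if model is None:
            raise ValueError("external mode requires a RiskModel")
        panel = list(model.panel)
    elif mode != "refit":
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for exam in cohort.exam_calendar.sort_index().index:
        cases = _complete_cases(cohort, exam, panel, stratum)
        try:
            surv = survival_after(cohort, exam)
        except ValueError:
            warnings.warn(f"trace ends at exam {exam}: no survivors")
            break
        ids = cases.index.intersection(surv.index)
        if len(ids) < max(min_n, len(panel) + 2):
            warnings.warn(
                f"trace ends at exam {exam}: only {len(ids)} usable subjects "
                f"in stratum {stratum!r}"
            )
            break
        X = cases.loc[ids, panel]
        y = surv.loc[ids]
        if mode == "refit":
            m = fit_composite(X, y, fit_exam=int(exam))
            res = evaluate_model(m, X, y)
        else:
            res = evaluate_model(model, X, y)
        rows.append(
            {
                "focal_exam": int(exam),
                "exam_year": float(cohort.exam_calendar.loc[exam]),
                "n": res.n,
                "r": res.r,
                "r2": res.r2,
                "p": res.p,
                "mode": mode if mode != "fixed" else f"fixed:{source_exam}",
                "sex_stratum": stratum,
            }
        )
    return pd.DataFrame(rows)
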