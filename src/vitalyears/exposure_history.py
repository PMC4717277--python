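"""Exam weighting, cumulative "variable-years" exposure, and rate-of-change
features.

Clinical exams are unevenly timed, so summing raw per-exam measurements
would weight densely-sampled periods too heavily.  The correction assigns
every calendar year the measurement of the *nearest* exam (piecewise
constant in time), after padding the first and last exams with half of the
average inter-exam period so the endpoints are not artificially
down-weighted.  Cumulative exposure is then the plain sum of annual values
over a window ending at the focal year, in variable-units x years — the
analog of pack-years of smoking.

Rate-of-change features (successive difference, three-point least-squares
slope, moving-average smoothed difference) are provided as first-class
alternatives so that rate-driven generative regimes are distinguishable
from cumulative ones in recovery studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import LongitudinalCohort


@dataclass
class AnnualSeries:
    """Piecewise-constant annual values of one variable for one subject.

    ``values[i]`` is the value assigned to calendar year ``year_start + i``;
    ``source_exam[i]`` is the (0-based) index of the contributing exam.
    The series is contiguous: length = year_end - year_start + 1.
    """

    variable: str
    year_start: int
    values: np.ndarray
    source_exam: np.ndarray

    @property
    def year_end(self) -> int:
        return self.year_start + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return self.year_start + np.arange(len(self.values))

    def value_at(self, year: int) -> float:
        if not self.year_start <= year <= self.year_end:
            raise KeyError(f"year {year} outside series span "
                           f"[{self.year_start}, {self.year_end}]")
        return float(self.values[int(year) - self.year_start])


def half_period_pad(exam_years: np.ndarray) -> int:
    """Half the average inter-exam period, rounded to whole years."""
    gaps = np.diff(np.sort(np.asarray(exam_years, dtype=float)))
    if len(gaps) == 0:
        raise ValueError("padding is undefined for a single exam; "
                         "pass pad_years explicitly")
    return int(round(float(np.mean(gaps)) / 2.0))


def assign_annual_values(
    exam_years,
    values,
    pad: bool = True,
    pad_years: int | None = None,
    variable: str = "",
) -> AnnualSeries:
    """Build the annual piecewise-constant series from (year, value) pairs.

    Each whole calendar year in the span takes the value of its nearest
    exam; a year equidistant from two exams takes the earlier one.  With
    ``pad=True`` the span extends beyond the first and last exam years by
    half the mean inter-exam gap (rounded to whole years), or by an
    explicit ``pad_years``.  Exams with missing values are dropped from the
    nearest-exam search.
    """
    years = np.asarray(exam_years, dtype=float)
    vals = np.asarray(values, dtype=float)
    keep = ~np.isnan(vals) & ~np.isnan(years)
    years, vals = years[keep], vals[keep]
    if len(years) == 0:
        raise ValueError("at least one measured exam is required")
    if len(np.unique(years)) != len(years):
        raise ValueError("exam years must be distinct")
    order = np.argsort(years)
    years, vals = years[order], vals[order]

    if pad:
        if pad_years is None:
            pad_years = half_period_pad(years)
    else:
        pad_years = 0
    start = int(round(years[0])) - pad_years
    end = int(round(years[-1])) + pad_years
    grid = np.arange(start, end + 1)

    dist = np.abs(grid[:, None] - years[None, :])
    src = np.argmin(dist, axis=1)  # argmin takes the first = earlier exam on ties
    return AnnualSeries(
        variable=variable,
        year_start=start,
        values=vals[src],
        source_exam=src,
    )


def cumulative_exposure(
    series: AnnualSeries,
    focal_year: int,
    depth_years: int,
    clip: bool = True,
) -> float:
    """Sum of annual values over the window ending at ``focal_year`` and
    reaching back ``depth_years`` years (inclusive), in
    variable-units x years.

    A window extending beyond the series span is clipped to it (with a
    warning) when ``clip`` is true, otherwise raises.
    """
    if depth_years < 1:
        raise ValueError("depth_years must be >= 1")
    lo = focal_year - depth_years + 1
    hi = focal_year
    if hi < series.year_start or lo > series.year_end:
        raise ValueError("window does not overlap the series span")
    if lo < series.year_start or hi > series.year_end:
        if not clip:
            raise ValueError("window extends beyond the series span")
        warnings.warn(
            f"window [{lo}, {hi}] clipped to series span "
            f"[{series.year_start}, {series.year_end}]",
            stacklevel=2,
        )
        lo, hi = max(lo, series.year_start), min(hi, series.year_end)
    i0 = lo - series.year_start
    i1 = hi - series.year_start + 1
    return float(np.sum(series.values[i0:i1]))


# ---------------------------------------------------------------------------
# Rate-of-change features (units/year)
# ---------------------------------------------------------------------------

def _clean_pairs(exam_years, values):
    years = np.asarray(exam_years, dtype=float)
    vals = np.asarray(values, dtype=float)
    return years, vals


def rate_successive(exam_years, values, focal: int) -> float:
    """Difference between the focal exam and its predecessor, per year.

    ``focal`` is a 0-based position in the measurement arrays.  Returns NaN
    (missing, not an error) when the focal exam or its predecessor is
    unmeasured.
    """
    years, vals = _clean_pairs(exam_years, values)
    if focal < 1 or focal >= len(vals):
        return float("nan")
    if np.isnan(vals[focal]) or np.isnan(vals[focal - 1]):
        return float("nan")
    return float((vals[focal] - vals[focal - 1]) / (years[focal] - years[focal - 1]))


def rate_threepoint(exam_years, values, focal: int) -> float:
    """Ordinary least-squares slope over the focal exam and its two
    predecessors; NaN when any of the three is unmeasured."""
    years, vals = _clean_pairs(exam_years, values)
    if focal < 2 or focal >= len(vals):
        return float("nan")
    y = vals[focal - 2 : focal + 1]
    x = years[focal - 2 : focal + 1]
    if np.isnan(y).any():
        return float("nan")
    xc = x - x.mean()
    return float(np.sum(xc * y) / np.sum(xc**2))


def rate_smoothed(exam_years, values, focal: int, window: int) -> float:
    """Moving-average smoothing before differencing: average ``window``
    adjacent exams (values and dates alike) in the two blocks ending at the
    focal exam, then take the successive-difference slope between the two
    smoothed points.  ``window=1`` reduces to :func:`rate_successive`."""
    if window < 1:
        raise ValueError("window must be >= 1")
    years, vals = _clean_pairs(exam_years, values)
    first = focal - 2 * window + 1
    if first < 0 or focal >= len(vals):
        return float("nan")
    block2 = slice(focal - window + 1, focal + 1)
    block1 = slice(first, focal - window + 1)
    if np.isnan(vals[block1]).any() or np.isnan(vals[block2]).any():
        return float("nan")
    y1, y2 = vals[block1].mean(), vals[block2].mean()
    t1, t2 = years[block1].mean(), years[block2].mean()
    return float((y2 - y1) / (t2 - t1))


# ---------------------------------------------------------------------------
# History-depth sweep
# ---------------------------------------------------------------------------

def history_sweep(
    cohort: LongitudinalCohort,
    variable: str,
    focal_exam: int,
    max_depth: int | None = None,
    stratum: str = "all",
    min_n: int = 30,
    pad: bool = True,
) -> pd.DataFrame:
    """Correlation of cumulative exposure with post-focal survival as
    progressively more exams of history are folded in.

    Depth 0 is the raw focal measurement (single-time correlation); depth d
    extends the cumulative window back to the wave date of exam
    ``focal_exam - d``, converted to years through the annual series.  The
    subject set is fixed across depths: survivors at the focal exam with a
    measured focal value and a known death date (windows reaching before a
    subject's first measurement are clipped to their padded span).

    Returns a tidy trace: variable, focal_exam, depth, window_start_year,
    r, r2, p, n, sex_stratum.
    """
    from .predictivity import survival_after, univariate_r2

    calendar = cohort.exam_calendar
    if focal_exam not in calendar.index:
        raise ValueError(f"focal exam {focal_exam} not in the exam calendar")
    focal_year = int(round(calendar.loc[focal_exam]))
    if max_depth is None:
        max_depth = focal_exam - 1
    max_depth = min(max_depth, focal_exam - 1)

    survival = survival_after(cohort, focal_exam)

    df = cohort.data
    hist = df.loc[
        (df["exam_index"] <= focal_exam) & df[variable].notna(),
        ["subject_id", "exam_index", "exam_year", variable],
    ]
    # per-subject numpy triples (exam indices, years, values), sorted by exam
    by_subject: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for sid, g in hist.groupby("subject_id", sort=False):
        by_subject[sid] = (
            g["exam_index"].to_numpy(dtype=int),
            g["exam_year"].to_numpy(dtype=float),
            g[variable].to_numpy(dtype=float),
        )

    eligible = [
        sid for sid, (idx, _, _) in by_subject.items()
        if idx[-1] == focal_exam and sid in survival.index
    ]
    if len(eligible) < min_n:
        warnings.warn(
            f"only {len(eligible)} usable subjects at focal exam {focal_exam}; "
            "trace not computed"
        )
        return pd.DataFrame(
            columns=["variable", "focal_exam", "depth", "window_start_year",
                     "r", "r2", "p", "n", "sex_stratum"]
        )
    if stratum != "all":
        sex = cohort.subject_table()["sex"]
        eligible = [sid for sid in eligible if sex.loc[sid] == stratum]

    # per-subject annual series values laid on a common year grid
    grid_start = int(round(calendar.iloc[0])) - 50  # generous left margin
    n_years = focal_year - grid_start + 1
    mat = np.zeros((len(eligible), n_years))
    focal_vals = np.empty(len(eligible))
    for i, sid in enumerate(eligible):
        idx, years, vals = by_subject[sid]
        series = assign_annual_values(
            years, vals, pad=pad,
            pad_years=None if len(years) > 1 else 1, variable=variable,
        )
        lo = max(series.year_start, grid_start)
        hi = min(series.year_end, focal_year)
        a, b = lo - grid_start, hi - grid_start + 1
        mat[i, a:b] = series.values[lo - series.year_start : hi - series.year_start + 1]
        focal_vals[i] = vals[-1]

    surv = survival.loc[eligible].to_numpy(dtype=float)
    rows = []
    for depth in range(0, max_depth + 1):
        if depth == 0:
            feature = focal_vals
            window_start = focal_year
        else:
            window_start = int(round(calendar.loc[focal_exam - depth]))
            a = window_start - grid_start
            feature = mat[:, a:].sum(axis=1)  # clipped: outside-span years are 0
        res = univariate_r2(feature, surv)
        rows.append(
            {
                "variable": variable,
                "focal_exam": focal_exam,
                "depth": depth,
                "window_start_year": window_start,
                "r": res.r,
                "r2": res.r2,
                "p": res.p,
                "n": res.n,
                "sex_stratum": stratum,
            }
        )
    return pd.DataFrame(rows)
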