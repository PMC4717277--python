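import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import vitalyears as vy
from vitalyears.cohort_io import REQUIRED_COLUMNS

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_long_df(subjects: dict) -> pd.DataFrame:
    """Build a long-format cohort table from a compact per-subject dict.

    ``subjects`` maps subject_id -> dict with keys sex, birth_year,
    death_year (or None) and exams: list of dicts with exam_index,
    exam_year and any measurement columns.
    """
    rows = []
    for sid, info in subjects.items():
        for exam in info["exams"]:
            row = {
                "subject_id": sid,
                "sex": info.get("sex", "male"),
                "birth_year": info.get("birth_year", 1915.0),
                "death_year": info.get("death_year", np.nan),
                "followup_complete": info.get("followup_complete", True),
                "bp_treated": exam.get("bp_treated", False),
            }
            for col in ("exam_index", "exam_year", "sbp", "dbp", "glucose",
                        "height_in", "weight_lb", "bmi"):
                row.setdefault(col, exam.get(col, np.nan))
            rows.append(row)
    df = pd.DataFrame(rows)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[REQUIRED_COLUMNS]


def full_exam(exam_index, exam_year, sbp=120.0, dbp=80.0, glucose=80.0,
              height_in=66.0, weight_lb=150.0, bmi=24.0, **kw):
    return dict(exam_index=exam_index, exam_year=exam_year, sbp=sbp, dbp=dbp,
                glucose=glucose, height_in=height_in, weight_lb=weight_lb,
                bmi=bmi, **kw)


@pytest.fixture
def toy_df() -> pd.DataFrame:
    """Two clean subjects, three exams each."""
    return make_long_df({
        "A": dict(sex="male", birth_year=1914.0, death_year=1990.0,
                  exams=[full_exam(1, 1948.0), full_exam(2, 1950.0),
                         full_exam(3, 1952.0)]),
        "B": dict(sex="female", birth_year=1916.0, death_year=1985.0,
                  exams=[full_exam(1, 1948.0, sbp=130.0), full_exam(2, 1950.0, sbp=132.0),
                         full_exam(3, 1952.0, sbp=134.0)]),
    })


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderately sized simulated cohort with full follow-up, shared by
    read-only tests (current-value regime, n=400, 28 waves)."""
    cohort, truth = vy.generate_cohort(vy.regime_config("current", n_subjects=400, seed=7))
    return cohort, truth


def build_exclusion_fixture(seed: int = 0):
    """A 1451-subject cohort engineered so that exactly 91 subjects fail
    follow-up, 10 lack a panel variable at exam 1, and 1 is an extreme
    systolic outlier (250 mm Hg at exam 1)."""
    cfg = vy.SimConfig(n_subjects=1451, missing_rate=0.0,
                       lost_to_followup_rate=0.0, rng_seed=seed)
    cohort, _ = vy.generate_cohort(cfg)
    df = cohort.data
    sids = np.sort(df["subject_id"].unique())
    lost, insufficient, outlier = sids[:91], sids[91:101], sids[101]

    is_lost = df["subject_id"].isin(lost)
    df.loc[is_lost, "death_year"] = np.nan
    df.loc[is_lost, "followup_complete"] = False
    df = df[~(is_lost & (df["exam_index"] == df["exam_index"].max()))]
    df.loc[df["subject_id"].isin(insufficient) & (df["exam_index"] == 1),
           "glucose"] = np.nan
    df.loc[(df["subject_id"] == outlier) & (df["exam_index"] == 1), "sbp"] = 250.0
    cohort.data = df.reset_index(drop=True)
    return cohort
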