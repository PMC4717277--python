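"""Correlation/regression machinery: oracle equivalences, invariants, and
focal sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vitalyears as vy
from vitalyears.predictivity import (
    CollinearPanelError,
    RiskModel,
    _complete_cases,
    crossval_r2,
    evaluate_model,
    fit_composite,
    focal_sweep,
    partial_correlation,
    survival_after,
    univariate_r2,
)

from conftest import full_exam, make_long_df


def _random_panel(rng, n, p=4, names=None):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=names or [f"v{i}" for i in range(p)])
    return X


# ---------------------------------------------------------------------------
# survival extraction
# ---------------------------------------------------------------------------

def test_survival_days_unit_convention():
    df = make_long_df({
        "A": dict(death_year=1958.0, exams=[full_exam(1, 1948.0)]),
        "B": dict(death_year=1960.0, exams=[full_exam(1, 1948.0)]),
    })
    surv = survival_after(vy.read_cohort(df), 1)
    assert surv.loc["A"] in (3652, 3653)  # 10 years at 365.25 d/yr


def test_survival_excludes_pre_focal_deaths():
    df = make_long_df({
        "A": dict(death_year=1949.0, exams=[full_exam(1, 1948.0), ]),
        "B": dict(death_year=1990.0, exams=[full_exam(1, 1948.0), full_exam(2, 1950.0)]),
    })
    surv = survival_after(vy.read_cohort(df), 2)
    assert list(surv.index) == ["B"]
    assert (surv > 0).all()


def test_survival_count_matches_attrition_summary(sim_cohort):
    """Cross-module consistency: survivors with known deaths at a focal
    exam equal the attrition table's living count (full follow-up)."""
    cohort, _ = sim_cohort
    summary = vy.summarize_cohort(cohort)
    for exam in (1, 10, 20):
        assert len(survival_after(cohort, exam)) == summary.loc[exam, "n_living"]


def test_survival_no_survivors_errors():
    df = make_long_df({"A": dict(death_year=1949.0, exams=[full_exam(1, 1948.0)])})
    cohort = vy.read_cohort(df)
    cohort.exam_calendar.loc[2] = 1950.0
    with pytest.raises(ValueError, match="no survivors"):
        survival_after(cohort, 2)


# ---------------------------------------------------------------------------
# univariate and partial correlation
# ---------------------------------------------------------------------------

def test_univariate_perfect_correlations():
    y = np.arange(10.0)
    assert univariate_r2(y, y).r == pytest.approx(1.0)
    assert univariate_r2(-y, y).r == pytest.approx(-1.0)
    assert univariate_r2(-y, y).r2 == pytest.approx(1.0)


def test_univariate_constant_feature_is_defined_missing():
    res = univariate_r2(np.ones(10), np.arange(10.0))
    assert not res.defined and "constant" in res.note
    assert np.isnan(res.r2)


def test_univariate_matches_textbook_formula():
    """r and the two-sided p from the t transform agree with explicit
    formulas to 1e-12 on random small vectors."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = rng.integers(5, 40)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = univariate_r2(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert abs(res.r - r) < 1e-12
        assert abs(res.r2 - r**2) < 1e-12
        assert abs(res.p - p) < 1e-12


def test_partial_correlation_empty_covariates_is_pearson():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=30), rng.normal(size=30)
    assert partial_correlation(x, y, np.empty((30, 0))) == pytest.approx(
        univariate_r2(x, y).r)


def test_partial_correlation_feature_among_covariates_errors():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=30), rng.normal(size=30)
    with pytest.raises(CollinearPanelError):
        partial_correlation(x, y, x.reshape(-1, 1))


def test_partial_correlation_matches_recursion_oracle():
    """First-order partial correlation satisfies the textbook recursion
    r_xy.z = (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2))."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        x, y, z = rng.normal(size=(3, 40))
        x = x + 0.5 * z
        y = y + 0.3 * z
        r_xy = stats.pearsonr(x, y)[0]
        r_xz = stats.pearsonr(x, z)[0]
        r_zy = stats.pearsonr(z, y)[0]
        oracle = (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz**2) * (1 - r_zy**2))
        assert abs(partial_correlation(x, y, z.reshape(-1, 1)) - oracle) < 1e-12


# ---------------------------------------------------------------------------
# composite models
# ---------------------------------------------------------------------------

def test_fit_exact_linear_data_recovers_weights():
    rng = np.random.default_rng(5)
    X = _random_panel(rng, 60, 4)
    beta = np.array([3.0, -2.0, 0.5, 10.0])
    y = X.to_numpy() @ beta + 1234.0
    model = fit_composite(X, y)
    np.testing.assert_allclose(model.weights, beta, atol=1e-8)
    assert model.intercept == pytest.approx(1234.0, abs=1e-6)
    assert evaluate_model(model, X, y).r2 == pytest.approx(1.0)


def test_fit_pulse_pressure_panel_collinearity_named():
    rng = np.random.default_rng(6)
    X = _random_panel(rng, 50, 2, names=["sbp", "dbp"])
    X["pulse_pressure"] = X["sbp"] - X["dbp"]
    y = rng.normal(size=50)
    with pytest.raises(CollinearPanelError) as err:
        fit_composite(X, y)
    assert {"sbp", "dbp", "pulse_pressure"} <= set(err.value.columns)


def test_fit_matches_normal_equations_oracle():
    """OLS weights agree with the pseudo-inverse solution to 1e-10."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        X = _random_panel(rng, 80, 5)
        y = rng.normal(size=80) * 100
        model = fit_composite(X, y)
        design = np.column_stack([X.to_numpy(), np.ones(80)])
        oracle = np.linalg.pinv(design) @ y
        np.testing.assert_allclose(model.weights, oracle[:-1], atol=1e-10)
        assert abs(model.intercept - oracle[-1]) < 1e-10


def test_fit_too_few_subjects_errors():
    X = _random_panel(np.random.default_rng(0), 5, 5)
    with pytest.raises(ValueError, match="subjects"):
        fit_composite(X, np.arange(5.0))


def test_evaluate_panel_mismatch_errors():
    rng = np.random.default_rng(8)
    X = _random_panel(rng, 30, 3)
    model = fit_composite(X, rng.normal(size=30))
    with pytest.raises(ValueError, match="panel"):
        evaluate_model(model, X.rename(columns={"v0": "other"}), np.zeros(30))


def test_evaluate_constant_prediction_is_defined_missing():
    model = RiskModel(panel=("v0",), weights=[0.0], intercept=5.0)
    res = evaluate_model(model, pd.DataFrame({"v0": np.arange(10.0)}), np.arange(10.0))
    assert not res.defined and "constant" in res.note


def test_univariate_equals_single_variable_model_r2():
    """Algebraic identity: the r^2 of a one-variable OLS model equals the
    squared Pearson correlation of that variable with the outcome."""
    rng = np.random.default_rng(9)
    x = rng.normal(size=200)
    y = 2 * x + rng.normal(size=200)
    X = pd.DataFrame({"x": x})
    model = fit_composite(X, y)
    assert evaluate_model(model, X, y).r2 == pytest.approx(
        univariate_r2(x, y).r2, abs=1e-12)


def test_weight_recovery_within_standard_errors():
    """On survival = linear(panel) + noise, fitted weights land within 3
    OLS standard errors of the generative weights in >= 95% of replicates."""
    rng = np.random.default_rng(10)
    beta = np.array([5.0, -3.0, 1.5, 0.0, 2.0, -1.0])
    hits = 0
    R = 200
    for _ in range(R):
        X = rng.normal(size=(300, 6))
        y = X @ beta + rng.normal(0, 10, 300)
        model = fit_composite(pd.DataFrame(X, columns=list("abcdef")), y)
        if np.all(np.abs(model.weights - beta) <= 3 * model.stderr[:-1]):
            hits += 1
    assert hits / R >= 0.95


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_crossval_perfect_linear_data():
    rng = np.random.default_rng(11)
    X = _random_panel(rng, 100, 3)
    y = X.to_numpy() @ [1.0, 2.0, 3.0] + 7.0
    assert crossval_r2(X, y, 5, seed=0).r2 == pytest.approx(1.0)


def test_crossval_deterministic_given_seed():
    rng = np.random.default_rng(12)
    X = _random_panel(rng, 200, 4)
    y = rng.normal(size=200)
    a = crossval_r2(X, y, 5, seed=3)
    b = crossval_r2(X, y, 5, seed=3)
    assert a.r2 == b.r2
    assert crossval_r2(X, y, 5, seed=4).r2 != a.r2


def test_crossval_below_in_sample_on_null_data():
    rng = np.random.default_rng(13)
    cv, ins = [], []
    for seed in range(20):
        X = _random_panel(rng, 400, 6)
        y = rng.normal(size=400)
        cv.append(crossval_r2(X, y, 5, seed=seed).r2)
        model = fit_composite(X, y)
        ins.append(evaluate_model(model, X, y).r2)
    assert np.mean(cv) < np.mean(ins)


def test_crossval_validates_arguments():
    X = _random_panel(np.random.default_rng(0), 12, 2)
    y = np.arange(12.0)
    with pytest.raises(ValueError):
        crossval_r2(X, y, 1, seed=0)
    with pytest.raises(ValueError):
        crossval_r2(X, y, 7, seed=0)


# ---------------------------------------------------------------------------
# focal sweeps
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_exam_cohort():
    cfg = vy.SimConfig(
        n_subjects=80, exam_count=2, rng_seed=21,
        trajectory_params=[vy.TrajectoryParams("dbp", 80.0, 10.0, 0.2, 0.0, 3.0)],
        hazard_params=vy.HazardParams(gompertz_a=3.5e-5, gompertz_b=0.094,
                                      beta_current=0.05, reference_value=80.0,
                                      driver="dbp"),
    )
    return vy.generate_cohort(cfg)[0]


def test_focal_sweep_two_exam_trace(two_exam_cohort):
    trace = focal_sweep(two_exam_cohort, mode="refit", panel=["dbp"], min_n=10)
    assert len(trace) == 2
    assert trace["n"].is_monotonic_decreasing
    assert ((trace["r2"] >= 0) & (trace["r2"] <= 1)).all()


def test_focal_sweep_fixed_equals_refit_at_source(sim_cohort):
    cohort, _ = sim_cohort
    refit = focal_sweep(cohort, mode="refit", panel=["dbp"], min_n=20)
    fixed = focal_sweep(cohort, mode="fixed", source_exam=5, panel=["dbp"], min_n=20)
    r_refit = refit.set_index("focal_exam")["r2"]
    r_fixed = fixed.set_index("focal_exam")["r2"]
    assert r_fixed.loc[5] == pytest.approx(r_refit.loc[5], abs=1e-12)


def test_focal_sweep_refit_upper_bounds_fixed(sim_cohort):
    """In-sample OLS optimality: the refit trace dominates any fixed-weight
    trace at every exam on the same data."""
    cohort, _ = sim_cohort
    refit = focal_sweep(cohort, mode="refit", panel=["dbp"], min_n=20)
    for src in (1, 15):
        fixed = focal_sweep(cohort, mode="fixed", source_exam=src,
                            panel=["dbp"], min_n=20)
        joined = refit.merge(fixed, on="focal_exam", suffixes=("_refit", "_fixed"))
        assert (joined["r2_refit"] >= joined["r2_fixed"] - 1e-12).all()


def test_focal_sweep_stratum_filter(sim_cohort):
    cohort, _ = sim_cohort
    males = focal_sweep(cohort, mode="refit", panel=["dbp"], stratum="male", min_n=20)
    assert (males["sex_stratum"] == "male").all()
    cases = _complete_cases(cohort, 1, ["dbp"], "male")
    assert males["n"].iloc[0] <= len(cases)


def test_focal_sweep_unknown_mode(sim_cohort):
    with pytest.raises(ValueError, match="mode"):
        focal_sweep(sim_cohort[0], mode="bogus")
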