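"""Synthetic longitudinal cohorts with known ground-truth hazard structure.

The generator emulates a mid-20th-century birth-decade cohort followed
through ~28 biennial exam waves: per-subject linear biomarker trajectories
(random baseline and drift) observed with measurement noise at shared exam
waves, and a Gompertz mortality hazard optionally modulated by the current
value, the accumulated exposure, or the rate of change of one driver
variable:

    h(t) = a * exp( b*t
                    + beta_current   * (x(t) - ref)
                    + beta_cumulative * integral_entry^t (x(s) - ref) ds
                    + beta_rate      * x'(t) )

with t the subject's age in years.  The three pure regimes (only one beta
nonzero) give downstream analyses a known answer to recover: rate-driven,
current-value-driven, and cumulative-exposure-driven mortality.

Latent paths are annual; an exam measurement is the latent value at the
nearest whole year plus Gaussian measurement noise.  Hazards are integrated
by yearly left-Riemann sums and death times drawn by exact inverse-CDF on
the resulting piecewise-constant hazard, so the constant-hazard limit is
exactly exponential.  Everyone dies by a hard cap age (default 120 years).

All default parameter values are chosen for statistical testability of the
downstream pipeline, not for physiological realism (no public description
of the real trajectory distributions exists); they are loosely anchored to
printed cohort summary statistics where available.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_io import PANEL, LongitudinalCohort, REQUIRED_COLUMNS

#: Hard cap on simulated lifespans (years); guarantees a fully deceased
#: cohort so the no-right-censoring analysis path always applies.
DEFAULT_CAP_AGE = 120.0

_LOG_HAZARD_LIMIT = 50.0


@dataclass(frozen=True)
class TrajectoryParams:
    """Linear-plus-noise annual trajectory of one variable.

    value(t) = baseline + drift * t + eps_t,  eps_t ~ N(0, noise_sd^2),
    with baseline ~ N(baseline_mean, baseline_sd^2) and
    drift ~ N(drift_mean, drift_sd^2) per subject, t in years since entry.
    """

    variable_name: str
    baseline_mean: float
    baseline_sd: float
    drift_mean: float = 0.0
    drift_sd: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        for name in ("baseline_sd", "drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class HazardParams:
    """Gompertz hazard with optional physiological modulation.

    gompertz_a is the baseline hazard (1/year) at age 0; gompertz_b the
    log-hazard slope with age (1/year).  The betas act on deviations of the
    driver variable from ``reference_value``: per unit (beta_current), per
    unit-year of accumulated exposure (beta_cumulative), or per unit/year of
    rate of change (beta_rate).  ``driver`` names the trajectory variable
    entering the hazard.
    """

    gompertz_a: float
    gompertz_b: float = 0.0
    beta_current: float = 0.0
    beta_cumulative: float = 0.0
    beta_rate: float = 0.0
    reference_value: float = 0.0
    driver: str | None = None

    def __post_init__(self):
        if not self.gompertz_a > 0:
            raise ValueError("gompertz_a must be > 0")
        if self.gompertz_b < 0:
            raise ValueError("gompertz_b must be >= 0")


def _default_trajectories() -> list[TrajectoryParams]:
    # Anchored loosely to printed exam-1 cohort summary statistics; sds and
    # drifts are testability choices.
    return [
        TrajectoryParams("sbp", 126.0, 13.0, 0.50, 0.20, 6.0),
        TrajectoryParams("dbp", 80.0, 9.0, 0.20, 0.10, 4.0),
        TrajectoryParams("glucose", 78.0, 14.0, 0.40, 0.20, 8.0),
        TrajectoryParams("height_in", 65.6, 3.5, -0.02, 0.0, 0.25),
        TrajectoryParams("weight_lb", 154.0, 27.0, 0.30, 0.30, 3.0),
        TrajectoryParams("bmi", 24.6, 3.9, 0.05, 0.05, 0.5),
    ]


@dataclass
class SimConfig:
    """Full description of one simulated study.

    The defaults emulate the study conditions the pipeline is built for:
    ~1349 subjects sharing a birth decade, first examined in 1948 at ages
    ~29-38, with 28 exam waves ~2 years apart.
    """

    n_subjects: int = 1349
    birth_year_low: float = 1910.0
    birth_year_high: float = 1919.0
    start_year: float = 1948.0
    exam_count: int = 28
    exam_spacing_mean: float = 2.0
    exam_spacing_jitter_sd: float = 0.25
    trajectory_params: list[TrajectoryParams] = field(default_factory=_default_trajectories)
    hazard_params: HazardParams = field(
        default_factory=lambda: HazardParams(
            gompertz_a=3.5e-5, gompertz_b=0.094,
            beta_current=0.02, reference_value=126.0, driver="sbp",
        )
    )
    missing_rate: float = 0.0
    lost_to_followup_rate: float = 0.0
    male_fraction: float = 0.468
    cap_age: float = DEFAULT_CAP_AGE
    rng_seed: int = 0

    def __post_init__(self):
        if self.birth_year_high - self.birth_year_low > 10:
            raise ValueError("birth window must span at most one decade")
        if self.exam_count < 2:
            raise ValueError("exam_count must be >= 2")
        for p in (self.missing_rate, self.lost_to_followup_rate, self.male_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        names = [t.variable_name for t in self.trajectory_params]
        if len(set(names)) != len(names):
            raise ValueError("trajectory variable names must be unique")
        hp = self.hazard_params
        if hp.driver is None:
            self.hazard_params = dataclasses.replace(hp, driver=names[0])
        elif hp.driver not in names:
            raise ValueError(f"hazard driver {hp.driver!r} not among trajectories")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["trajectory_params"] = [TrajectoryParams(**t) for t in d.get("trajectory_params", [])]
        if "hazard_params" in d:
            d["hazard_params"] = HazardParams(**d["hazard_params"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def regime(self) -> str:
        hp = self.hazard_params
        active = [
            name for name, b in [
                ("rate", hp.beta_rate),
                ("current", hp.beta_current),
                ("cumulative", hp.beta_cumulative),
            ] if b != 0.0
        ]
        if not active:
            return "age_only"
        return active[0] if len(active) == 1 else "mixed"


# ---------------------------------------------------------------------------
# Calendar and trajectories
# ---------------------------------------------------------------------------

def sample_exam_calendar(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Exam wave dates (calendar years) shared by all subjects.

    Gaps are Gaussian around ``exam_spacing_mean``; a non-positive gap is
    resampled so dates are always strictly increasing.  Deterministic given
    ``config.rng_seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 11]))
    years = [float(config.start_year)]
    for _ in range(config.exam_count - 1):
        gap = rng.normal(config.exam_spacing_mean, config.exam_spacing_jitter_sd)
        while gap <= 0:
            gap = rng.normal(config.exam_spacing_mean, config.exam_spacing_jitter_sd)
        years.append(years[-1] + gap)
    return np.asarray(years)


@dataclass
class TrajectoryPath:
    """One subject's simulated annual path: noisy observable values plus
    the smooth latent component and its generating coefficients."""

    values: np.ndarray   # baseline + drift*t + noise_t
    smooth: np.ndarray   # baseline + drift*t
    baseline: float
    drift: float

    def __len__(self) -> int:
        return len(self.values)


def simulate_trajectory(
    params: TrajectoryParams,
    rng: np.random.Generator,
    horizon: int,
) -> TrajectoryPath:
    """Simulate one annual trajectory of length ``horizon`` (years)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1 year")
    baseline = rng.normal(params.baseline_mean, params.baseline_sd) if params.baseline_sd else params.baseline_mean
    drift = rng.normal(params.drift_mean, params.drift_sd) if params.drift_sd else params.drift_mean
    t = np.arange(horizon, dtype=float)
    smooth = baseline + drift * t
    noise = rng.normal(0.0, params.noise_sd, horizon) if params.noise_sd else np.zeros(horizon)
    return TrajectoryPath(values=smooth + noise, smooth=smooth, baseline=baseline, drift=drift)


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

def _log_hazard_grid(
    ages: np.ndarray,
    smooth: np.ndarray,
    drift: np.ndarray,
    hazard: HazardParams,
) -> np.ndarray:
    """Yearly log-hazard on an (n, H) grid of ages.

    The cumulative term is a left-Riemann sum of (x - ref): exposure
    accumulated strictly before each grid year.
    """
    dev = smooth - hazard.reference_value
    cum = np.cumsum(dev, axis=-1) - dev  # exclusive prefix sum
    logh = (
        math.log(hazard.gompertz_a)
        + hazard.gompertz_b * ages
        + hazard.beta_current * dev
        + hazard.beta_cumulative * cum
        + hazard.beta_rate * drift[..., None] * np.ones_like(ages)
    )
    if np.nanmax(logh) > _LOG_HAZARD_LIMIT:
        terms = {
            "beta_current": np.nanmax(np.abs(hazard.beta_current * dev)),
            "beta_cumulative": np.nanmax(np.abs(hazard.beta_cumulative * cum)),
            "beta_rate": abs(hazard.beta_rate) * float(np.nanmax(np.abs(drift))),
        }
        worst = max(terms, key=terms.get)
        raise OverflowError(
            f"hazard overflow: log-hazard exceeds {_LOG_HAZARD_LIMIT}; "
            f"largest modulation term is {worst}"
        )
    return logh


def _sample_death_ages(
    entry_age: np.ndarray,
    logh: np.ndarray,
    rng: np.random.Generator,
    cap_age: float,
) -> np.ndarray:
    """Exact inverse-CDF draw from the piecewise-constant yearly hazard.

    Grid column t covers ages [entry+t, entry+t+1).  Subjects whose target
    cumulative hazard is never reached die at the cap age.
    """
    h = np.exp(logh)
    # zero out hazard beyond the cap so the cap is the only escape
    ages = entry_age[:, None] + np.arange(logh.shape[1])[None, :]
    h = np.where(ages < cap_age, h, 0.0)
    cum = np.cumsum(h, axis=1)
    target = -np.log(rng.uniform(size=logh.shape[0]))
    idx = (cum < target[:, None]).sum(axis=1)  # first year where cum >= target
    death = np.full(logh.shape[0], cap_age)
    hit = idx < logh.shape[1]
    i = np.where(hit)[0]
    j = idx[hit]
    prev = np.where(j > 0, cum[i, np.maximum(j - 1, 0)], 0.0)
    frac = (target[hit] - prev) / h[i, j]
    death[hit] = entry_age[hit] + j + frac
    return np.minimum(death, cap_age)


def simulate_death(
    path: TrajectoryPath,
    hazard: HazardParams,
    entry_age: float,
    rng: np.random.Generator,
    cap_age: float = DEFAULT_CAP_AGE,
) -> float:
    """Draw one death age (> entry_age, <= cap_age) for a subject whose
    driver-variable path covers [entry_age, cap_age] on an annual grid."""
    H = len(path)
    ages = entry_age + np.arange(H, dtype=float)
    logh = _log_hazard_grid(ages[None, :], path.smooth[None, :], np.asarray([path.drift]), hazard)
    return float(_sample_death_ages(np.asarray([entry_age]), logh, rng, cap_age)[0])


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent state the observable cohort was generated from, kept apart
    so recovery analyses cannot accidentally touch it."""

    table: pd.DataFrame                 # one row per subject
    latent: dict[str, np.ndarray]       # variable -> (n, H) smooth paths
    entry_age: np.ndarray               # (n,)
    age_offsets: np.ndarray             # (H,) years since entry
    config: SimConfig

    @property
    def regime(self) -> str:
        return self.config.regime


def generate_cohort(config: SimConfig) -> tuple[LongitudinalCohort, GroundTruth]:
    """Generate an observable cohort plus its ground truth, fully
    reproducible from ``config.rng_seed``.

    Measurements exist only at waves a subject survives to attend; loss to
    follow-up truncates a subject's record at a random wave and hides the
    death date; missingness then knocks out individual measurements.
    """
    ss = np.random.SeedSequence([config.rng_seed, 7])
    r_cal, r_subj, r_death, r_obs = [np.random.default_rng(s) for s in ss.spawn(4)]

    calendar = sample_exam_calendar(config, rng=r_cal)
    n = config.n_subjects
    birth = r_subj.uniform(config.birth_year_low, config.birth_year_high, n)
    sex = np.where(r_subj.uniform(size=n) < config.male_fraction, "male", "female")
    entry_age = calendar[0] - birth

    H = int(np.ceil(config.cap_age - entry_age.min())) + 1
    t = np.arange(H, dtype=float)
    ages = entry_age[:, None] + t[None, :]

    latent: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    drifts: dict[str, np.ndarray] = {}
    noise_sd: dict[str, float] = {}
    for tp in config.trajectory_params:
        b = r_subj.normal(tp.baseline_mean, tp.baseline_sd, n)
        d = r_subj.normal(tp.drift_mean, tp.drift_sd, n)
        latent[tp.variable_name] = b[:, None] + d[:, None] * t[None, :]
        baselines[tp.variable_name] = b
        drifts[tp.variable_name] = d
        noise_sd[tp.variable_name] = tp.noise_sd

    driver = config.hazard_params.driver
    logh = _log_hazard_grid(ages, latent[driver], drifts[driver], config.hazard_params)
    death_age = _sample_death_ages(entry_age, logh, r_death, config.cap_age)
    death_year = birth + death_age

    lost = r_obs.uniform(size=n) < config.lost_to_followup_rate
    dropout_wave = r_obs.integers(2, config.exam_count + 1, size=n)  # 1-based wave index

    # measurement noise drawn per wave (annual grid column shared by all
    # subjects because the calendar is shared)
    wave_t = np.rint(calendar - calendar[0]).astype(int)
    meas_noise = {
        v: r_obs.normal(0.0, noise_sd[v], (n, config.exam_count)) if noise_sd[v] else np.zeros((n, config.exam_count))
        for v in latent
    }
    missing = (
        r_obs.uniform(size=(n, config.exam_count, len(latent))) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n, config.exam_count, len(latent)), dtype=bool)
    )

    var_names = list(latent)
    subject_id = np.array([f"S{i:05d}" for i in range(n)])
    frames: list[pd.DataFrame] = []
    for k, wave_year in enumerate(calendar):
        alive = death_year > wave_year
        attending = alive & (~lost | (dropout_wave > k + 1))
        idx = np.where(attending)[0]
        if idx.size == 0:
            continue
        cols = {
            "subject_id": subject_id[idx],
            "sex": sex[idx],
            "birth_year": birth[idx],
            "death_year": np.where(lost[idx], np.nan, death_year[idx]),
            "followup_complete": ~lost[idx],
            "exam_index": np.full(idx.size, k + 1),
            "exam_year": np.full(idx.size, wave_year),
            "bp_treated": np.zeros(idx.size, dtype=bool),
        }
        for vi, v in enumerate(var_names):
            vals = latent[v][idx, wave_t[k]] + meas_noise[v][idx, k]
            cols[v] = np.where(missing[idx, k, vi], np.nan, vals)
        frames.append(pd.DataFrame(cols))

    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(["subject_id", "exam_index"], kind="stable").reset_index(drop=True)
    for col in REQUIRED_COLUMNS:
        if col not in data.columns:
            data[col] = np.nan
    data = data[REQUIRED_COLUMNS]
    data["followup_complete"] = data["followup_complete"].astype("boolean")
    data["bp_treated"] = data["bp_treated"].astype("boolean")
    data["exam_index"] = data["exam_index"].astype("Int64")

    cohort = LongitudinalCohort(
        data=data,
        exam_calendar=pd.Series(calendar, index=pd.Index(range(1, config.exam_count + 1), name="exam_index"), name="exam_year"),
        variable_panel=[v for v in PANEL if v in latent] or var_names,
    )

    truth_cols = {
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "sex": sex,
        "birth_year": birth,
        "entry_age": entry_age,
        "death_age": death_age,
        "death_year": death_year,
        "lost_to_followup": lost,
        "dropout_wave": dropout_wave,
    }
    for v in var_names:
        truth_cols[f"{v}_baseline"] = baselines[v]
        truth_cols[f"{v}_drift"] = drifts[v]
    truth = GroundTruth(
        table=pd.DataFrame(truth_cols),
        latent=latent,
        entry_age=entry_age,
        age_offsets=t,
        config=config,
    )
    return cohort, truth


def write_simulation(outdir, cohort: LongitudinalCohort, truth: GroundTruth) -> dict[str, Path]:
    """Write cohort CSV, ground-truth sidecar CSV and the config YAML."""
    from .cohort_io import write_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "config": outdir / "sim_config.yaml",
    }
    write_cohort(cohort, paths["cohort"])
    truth.table.to_csv(paths["ground_truth"], index=False)
    truth.config.to_yaml(paths["config"])
    return paths


# ---------------------------------------------------------------------------
# Named generative regimes for recovery studies
# ---------------------------------------------------------------------------

def regime_config(kind: str, n_subjects: int = 1500, seed: int = 0) -> SimConfig:
    """Single-driver study configurations with a known hazard regime.

    ``kind`` is one of 'cumulative', 'current', 'rate' (only the matching
    beta nonzero), 'frailty' (a current-value regime with strong hazard
    heterogeneity, for survivorship-bias studies), or 'age_only' (pure
    Gompertz).  Trajectory spreads and
    effect sizes are designed so each regime's observable signature is
    identifiable under the linear-trajectory model (see the methods note):
    the current regime has no drift heterogeneity, so once measurement
    noise is averaged away extra history carries no further signal; the
    cumulative regime carries large measurement noise and mild drift
    spread, so accumulated history keeps adding signal at every depth; the
    rate regime hides its drift signal under a wide baseline spread that
    masks cumulative features but not direct rate estimates.
    """
    base = dict(gompertz_a=3.5e-5, gompertz_b=0.094, reference_value=80.0, driver="dbp")
    traj = {
        "cumulative": TrajectoryParams("dbp", 80.0, 10.0, 0.2, 0.15, 8.0),
        "current": TrajectoryParams("dbp", 80.0, 10.0, 0.2, 0.0, 3.0),
        "rate": TrajectoryParams("dbp", 80.0, 15.0, 0.2, 0.30, 2.0),
        "frailty": TrajectoryParams("dbp", 80.0, 12.0, 0.2, 0.0, 3.0),
        "age_only": TrajectoryParams("dbp", 80.0, 10.0, 0.2, 0.15, 4.0),
    }
    betas = {
        "cumulative": dict(beta_cumulative=0.0015),
        "current": dict(beta_current=0.04),
        "rate": dict(beta_rate=1.6),
        "frailty": dict(beta_current=0.10),
        "age_only": {},
    }
    if kind not in betas:
        raise ValueError(f"unknown regime {kind!r}")
    if kind == "frailty":
        base["gompertz_b"] = 0.085  # slower age term so selection dominates
    return SimConfig(
        n_subjects=n_subjects,
        trajectory_params=[traj[kind]],
        hazard_params=HazardParams(**base, **betas[kind]),
        rng_seed=seed,
    )
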