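"""End-to-end pipeline runs with configuration snapshots, structured
logging, and figure-shaped outputs.

A run ties the stages together — simulate (optional), prepare (read,
derive, exclude), composite fit with cross-validation, focal-exam sweeps
and history-depth sweeps — and writes every numeric table as CSV plus
models as JSON under a deterministic run id, so identical seeds give
byte-identical numeric outputs.  Per-stage subject counts are logged so
attrition is always auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_io, exposure_history, predictivity, synthetic_cohort
from .cohort_io import ExclusionCriteria, PANEL

logger = logging.getLogger("vitalyears")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``cohort_csv`` points at an existing long-format cohort or
    ``simulate`` holds a :class:`~vitalyears.synthetic_cohort.SimConfig`
    dict to generate one.  A snapshot of the resolved config is always
    written next to the outputs.
    """

    out_dir: str = "run_out"
    cohort_csv: str | None = None
    simulate: dict | None = None
    criteria: dict = field(default_factory=dict)
    panel: list[str] = field(default_factory=lambda: list(PANEL))
    composite_exam: int = 1
    cv_folds: int = 5
    focal_modes: list[str] = field(default_factory=lambda: ["refit", "fixed:1"])
    strata: list[str] = field(default_factory=lambda: ["all"])
    history: list[dict] = field(default_factory=list)  # {variable, focal_exam, max_depth}
    seed: int = 0
    bp_adjust: dict | None = None  # {delta_sbp, delta_dbp, scope}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def run_id(self) -> str:
        digest = hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:8]
        return f"run-s{self.seed}-{digest}"


@dataclass
class RunBundle:
    run_id: str
    out_dir: Path
    paths: dict[str, Path]

    def table(self, key: str) -> pd.DataFrame:
        return pd.read_csv(self.paths[key])


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the full pipeline described by ``config``.

    Deterministic given the seeds in the config; every output file name
    carries the run id.  Raises :class:`StageError` naming the failing
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rid = config.run_id()
    paths: dict[str, Path] = {}

    handler = logging.FileHandler(out / f"{rid}.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def _path(key: str, name: str) -> Path:
        p = out / f"{rid}_{name}"
        paths[key] = p
        return p

    try:
        # resolved-config snapshot
        snap = _path("config", "config.yaml")
        snap.write_text(yaml.safe_dump({"run_id": rid, **asdict(config)}, sort_keys=False))

        # --- simulate or load -------------------------------------------
        try:
            if config.simulate is not None:
                sim = dict(config.simulate)
                sim.setdefault("rng_seed", config.seed)
                sc = synthetic_cohort.SimConfig.from_dict(sim)
                cohort, truth = synthetic_cohort.generate_cohort(sc)
                cohort_io.write_cohort(cohort, _path("cohort", "cohort.csv"))
                truth.table.to_csv(_path("ground_truth", "ground_truth.csv"), index=False)
                logger.info("simulate: %d subjects, %d waves", cohort.n_subjects, sc.exam_count)
            elif config.cohort_csv:
                cohort = cohort_io.read_cohort(config.cohort_csv)
                logger.info("load: %d subjects from %s", cohort.n_subjects, config.cohort_csv)
            else:
                raise ValueError("config needs either cohort_csv or simulate")
        except Exception as e:
            raise StageError("input", e) from e

        # --- prepare ------------------------------------------------------
        try:
            cohort = cohort_io.derive_variables(cohort)
            if config.bp_adjust:
                cohort = cohort_io.adjust_bp_treatment(
                    cohort,
                    config.bp_adjust.get("delta_sbp", 0.0),
                    config.bp_adjust.get("delta_dbp", 0.0),
                    config.bp_adjust.get("scope", "treated_only"),
                )
            crit_kwargs = dict(config.criteria)
            # completeness is judged on the cohort's own panel unless the
            # config says otherwise
            crit_kwargs.setdefault("required_vars", tuple(cohort.variable_panel))
            criteria = ExclusionCriteria(**crit_kwargs)
            retained, report = cohort_io.apply_exclusions(cohort, criteria)
            report.to_json(_path("exclusions_json", "exclusions.json"))
            report.to_csv(_path("exclusions_csv", "exclusions.csv"))
            cohort_io.write_cohort(retained, _path("prepared", "prepared.csv"))
            summary = cohort_io.summarize_cohort(retained)
            summary.to_csv(_path("summary", "summary.csv"))
            logger.info("prepare: retained %d of %d subjects", report.n_retained, report.n_input)
        except Exception as e:
            raise StageError("prepare", e) from e

        # --- composite ----------------------------------------------------
        try:
            exam = config.composite_exam
            cases = predictivity._complete_cases(retained, exam, config.panel, "all")
            surv = predictivity.survival_after(retained, exam)
            ids = cases.index.intersection(surv.index)
            X, y = cases.loc[ids, config.panel], surv.loc[ids]
            model = predictivity.fit_composite(X, y, fit_exam=exam)
            insample = predictivity.evaluate_model(model, X, y)
            cv = predictivity.crossval_r2(X, y, config.cv_folds, seed=config.seed)
            payload = {
                **model.to_dict(),
                "in_sample_r2": insample.r2,
                "in_sample_p": insample.p,
                "cv_r2": cv.r2,
                "cv_folds": config.cv_folds,
                "seed": config.seed,
            }
            _path("model", "composite.json").write_text(json.dumps(payload, indent=2) + "\n")
            logger.info("composite: exam %d n=%d r2=%.4f cv_r2=%.4f",
                        exam, len(ids), insample.r2, cv.r2)
        except Exception as e:
            raise StageError("composite", e) from e

        # --- focal sweeps -------------------------------------------------
        try:
            traces = []
            for stratum in config.strata:
                for mode in config.focal_modes:
                    if mode.startswith("fixed"):
                        src = int(mode.split(":", 1)[1]) if ":" in mode else 1
                        tr = predictivity.focal_sweep(
                            retained, mode="fixed", source_exam=src,
                            panel=config.panel, stratum=stratum)
                    else:
                        tr = predictivity.focal_sweep(
                            retained, mode="refit", panel=config.panel, stratum=stratum)
                    traces.append(tr)
            focal = pd.concat(traces, ignore_index=True) if traces else pd.DataFrame()
            focal.to_csv(_path("focal_traces", "focal_traces.csv"), index=False)
            logger.info("focal-sweep: %d trace rows", len(focal))
        except Exception as e:
            raise StageError("focal-sweep", e) from e

        # --- history sweeps ----------------------------------------------
        try:
            htraces = []
            for spec_ in config.history:
                htraces.append(
                    exposure_history.history_sweep(
                        retained,
                        variable=spec_["variable"],
                        focal_exam=int(spec_["focal_exam"]),
                        max_depth=spec_.get("max_depth"),
                        stratum=spec_.get("stratum", "all"),
                    )
                )
            hist = pd.concat(htraces, ignore_index=True) if htraces else pd.DataFrame()
            hist.to_csv(_path("history_traces", "history_traces.csv"), index=False)
            logger.info("history-sweep: %d trace rows", len(hist))
        except Exception as e:
            raise StageError("history-sweep", e) from e
    finally:
        logger.removeHandler(handler)
        handler.close()
    paths["log"] = out / f"{rid}.log"
    return RunBundle(run_id=rid, out_dir=out, paths=paths)


def render_report(bundle: RunBundle) -> Path:
    """Render plots and a markdown summary from a completed run bundle.

    One figure per trace family (survival curve, focal traces, history
    traces); numeric tables are always written into the markdown even if a
    figure cannot be drawn.  Idempotent: re-rendering from the same bundle
    reproduces identical tables.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = bundle.out_dir
    rid = bundle.run_id
    sections: list[str] = [f"# vitalyears report `{rid}`", ""]

    def _figure(name: str) -> Path:
        return out / f"{rid}_{name}.png"

    # survival curve from the attrition summary
    summary = bundle.table("summary")
    sections += ["## Surviving subcohort", "", summary.to_markdown(index=False), ""]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.step(summary["exam_year"], summary["n_living"], where="post")
    ax.set_xlabel("calendar year")
    ax.set_ylabel("living subjects")
    fig.tight_layout()
    fig.savefig(_figure("survival"))
    plt.close(fig)
    sections.append(f"![survival]({_figure('survival').name})\n")

    for key, title, xcol in [
        ("focal_traces", "Focal-exam predictivity", "exam_year"),
        ("history_traces", "History-depth predictivity", "depth"),
    ]:
        df = bundle.table(key) if bundle.paths[key].exists() else pd.DataFrame()
        sections.append(f"## {title}\n")
        if df.empty:
            sections.append("_empty trace_\n")
            fig, ax = plt.subplots(figsize=(4, 2.5))
            ax.text(0.5, 0.5, "no data", ha="center", va="center")
            ax.set_axis_off()
            fig.savefig(_figure(key))
            plt.close(fig)
            continue
        sections += [df.to_markdown(index=False), ""]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        groups = df.groupby([c for c in ("mode", "variable", "focal_exam", "sex_stratum")
                             if c in df.columns], dropna=False)
        for name, g in groups:
            ax.plot(g[xcol], g["r2"], marker="o", ms=3,
                    label="/".join(str(v) for v in np.atleast_1d(name)))
        ax.set_xlabel(xcol)
        ax.set_ylabel(r"$r^2$ with future survival")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(_figure(key))
        plt.close(fig)
        sections.append(f"![{key}]({_figure(key).name})\n")

    md = out / f"{rid}_report.md"
    md.write_text("\n".join(sections))
    return md
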