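"""End-to-end study pipeline: simulate → preprocess → features →
frequentist + machine-learning evaluation.

:class:`StressStudy` is the model object: built from a cohort (recorded
or simulated), its :meth:`StressStudy.fit` runs the full analysis and
returns a :class:`StudyResults` carrying per-task exclusion reports,
feature tables, mixed-ANOVA tables with their Bonferroni thresholds, the
self-report manipulation check and the 3 algorithms × 2 design modes
machine-learning grid, with ``summary()`` and ``save()``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import MixedAnova, bonferroni
from .cohort import CohortDataset, Stage, Task
from .features import COMMON_FEATURES, TASK_FEATURES, extract_features
from .ml import ModelSpec, fit_predict_cv, run_model_grid
from .preprocess import exclude_outliers
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StressStudy",
    "StudyResults",
    "featurize_cohort",
    "manipulation_check",
    "run_full_analysis",
    "run_task_separability_probe",
]


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    n_perm: int = 500
    cv_folds: int = 5
    targets: tuple[str, ...] = ("condition",)
    run_ml: bool = True
    render_images: bool = False


@dataclass
class PipelineConfig:
    """Full pipeline configuration; the global seed drives every stage."""

    simulation: SimConfig = field(default_factory=SimConfig)
    dt_ms: float = 15.0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed deterministically seeds the simulation too
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            from .simulate import EffectParams, MovementParams

            if "movement" in sim:
                sim["movement"] = MovementParams(**sim["movement"])
            if "effects" in sim:
                sim["effects"] = EffectParams(**sim["effects"])
            for key in ("rate_range_hz", "screen", "tasks"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimConfig(**sim)
        if "analysis" in raw:
            a = dict(raw["analysis"])
            if "targets" in a:
                a["targets"] = tuple(a["targets"])
            raw["analysis"] = AnalysisConfig(**a)
        return cls(**raw)


def featurize_cohort(
    cohort: CohortDataset, task: Task, dt: float = 15.0
) -> pd.DataFrame:
    """Tidy feature table for one task: one row per (pid, stage).

    Columns: pid, task, stage, condition, the task's applicable features,
    and the SAM valence/arousal ratings for the task.  Sessions whose
    feature extraction fails are dropped with a warning.
    """
    task = Task(task)
    rows = []
    for s in cohort.sessions_for(task):
        try:
            fv = extract_features(s, dt=dt)
        except (ValueError, KeyError) as exc:
            logger.warning("dropping session %s: %s", s.key, exc)
            continue
        row = {
            "pid": s.participant_id,
            "task": task.value,
            "stage": s.stage.value,
            "condition": s.condition.value,
            **fv.values,
        }
        rep = cohort.reports.get((s.participant_id, s.stage))
        if rep is not None and task in rep.sam:
            row["valence"], row["arousal"] = rep.sam[task]
        rows.append(row)
    return pd.DataFrame(rows)


def anova_table_for_task(
    features: pd.DataFrame, task: Task, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature 2×2 mixed ANOVA with the task's Bonferroni threshold."""
    task = Task(task)
    names = TASK_FEATURES[task]
    corrected = bonferroni(alpha, len(names))
    rows = []
    for name in names:
        wide = features.pivot_table(
            index=["pid", "condition"], columns="stage", values=name
        ).dropna()
        if len(wide) < 4:
            continue
        wide = wide.reset_index()
        try:
            model = MixedAnova(
                baseline=wide["baseline"],
                application=wide["application"],
                group=wide["condition"],
            )
        except ValueError as exc:  # e.g. a condition group of one
            logger.warning("skipping ANOVA for %s/%s: %s", task.value, name, exc)
            continue
        res = model.fit()
        for eff in res.effects.values():
            rows.append(
                {
                    "task": task.value,
                    "feature": name,
                    "effect": eff.effect,
                    "F": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "eta2_part": eff.eta2_part,
                    "alpha_corrected": corrected,
                    "sig_corrected": eff.p < corrected,
                    "sig_uncorrected": eff.p < alpha,
                }
            )
    return pd.DataFrame(rows)


def manipulation_check(cohort: CohortDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Mixed ANOVAs on every self-report measure (condition × stage)."""
    measures: dict[str, dict[tuple[str, Stage], float]] = {}
    for (pid, stage), rep in cohort.reports.items():
        for name, value in (
            ("good_bad", rep.good_bad),
            ("rest_unrest", rep.rest_unrest),
            ("alert_tired", rep.alert_tired),
            ("stress", rep.stress_item),
            ("nostalgia", rep.nostalgia_item),
        ):
            measures.setdefault(name, {})[(pid, stage)] = value
        for task, (val, aro) in rep.sam.items():
            measures.setdefault(f"valence_{task.value}", {})[(pid, stage)] = val
            measures.setdefault(f"arousal_{task.value}", {})[(pid, stage)] = aro

    rows = []
    for name, data in measures.items():
        pids = sorted(
            {
                pid
                for (pid, st) in data
                if (pid, Stage.BASELINE) in data and (pid, Stage.APPLICATION) in data
            }
        )
        if len(pids) < 4:
            continue
        base = [data[(p, Stage.BASELINE)] for p in pids]
        app = [data[(p, Stage.APPLICATION)] for p in pids]
        group = [cohort.condition_of(p).value for p in pids]
        try:
            res = MixedAnova(base, app, group).fit()
        except ValueError as exc:
            logger.warning("skipping manipulation check for %s: %s", name, exc)
            continue
        for eff in res.effects.values():
            rows.append(
                {
                    "measure": name,
                    "effect": eff.effect,
                    "F": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "eta2_part": eff.eta2_part,
                    "sig": eff.p < alpha,
                }
            )
    return pd.DataFrame(rows)


class StudyResults:
    """Everything :meth:`StressStudy.fit` produced, with save/summary."""

    def __init__(
        self,
        config: PipelineConfig,
        exclusions: dict[Task, pd.DataFrame],
        feature_tables: dict[Task, pd.DataFrame],
        anova_tables: dict[Task, pd.DataFrame],
        manipulation: pd.DataFrame,
        ml_tables: dict[Task, pd.DataFrame],
    ):
        self.config = config
        self.exclusions = exclusions
        self.feature_tables = feature_tables
        self.anova_tables = anova_tables
        self.manipulation = manipulation
        self.ml_tables = ml_tables

    def significance_counts(self) -> dict:
        counts = {"corrected": 0, "uncorrected": 0, "n_tests": 0}
        for table in self.anova_tables.values():
            if table.empty:
                continue
            inter = table[table["effect"] == "interaction"]
            counts["n_tests"] += len(inter)
            counts["corrected"] += int(inter["sig_corrected"].sum())
            counts["uncorrected"] += int(inter["sig_uncorrected"].sum())
        return counts

    def summary(self) -> str:
        lines = ["Stress study analysis", "=" * 40]
        c = self.significance_counts()
        lines.append(
            f"Feature-level interaction tests: {c['n_tests']} "
            f"({c['corrected']} significant at corrected alpha, "
            f"{c['uncorrected']} at .05)"
        )
        if not self.manipulation.empty:
            inter = self.manipulation[self.manipulation["effect"] == "interaction"]
            sig = int(inter["sig"].sum())
            lines.append(
                f"Manipulation check: {sig}/{len(inter)} self-report "
                "interaction effects significant at .05"
            )
        for task, table in self.ml_tables.items():
            if table is None or table.empty:
                continue
            best = table.loc[table["score"].idxmax()]
            lines.append(
                f"ML best for {task.value}: {best['algorithm']} "
                f"({best['design_mode']}) score {best['score']:.3f}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for task in self.feature_tables:
            stem = task.value
            self.exclusions[task].to_csv(out / f"exclusions_{stem}.csv", index=False)
            self.feature_tables[task].to_csv(out / f"features_{stem}.csv", index=False)
            self.anova_tables[task].to_csv(out / f"anova_{stem}.csv", index=False)
            if self.ml_tables.get(task) is not None:
                self.ml_tables[task].to_csv(out / f"ml_{stem}.csv", index=False)
        self.manipulation.to_csv(out / "manipulation_check.csv", index=False)
        summary = {
            "interaction_significance": self.significance_counts(),
            "seed": self.config.seed,
            "n_participants": self.config.simulation.n_participants,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


class StressStudy:
    """Study model: a cohort plus the analysis configuration.

    Examples
    --------
    >>> cfg = PipelineConfig(seed=7)
    >>> cfg.simulation.n_participants = 12
    >>> study = StressStudy.from_simulation(cfg)   # doctest: +SKIP
    >>> results = study.fit()                      # doctest: +SKIP
    >>> print(results.summary())                   # doctest: +SKIP
    """

    def __init__(self, cohort: CohortDataset, config: PipelineConfig | None = None):
        self.cohort = cohort
        self.config = config or PipelineConfig()

    @classmethod
    def from_simulation(cls, config: PipelineConfig) -> "StressStudy":
        return cls(simulate_cohort(config.simulation), config)

    def fit(self) -> StudyResults:
        cfg = self.config
        tasks = [Task(t) for t in cfg.simulation.tasks]
        exclusions: dict[Task, pd.DataFrame] = {}
        feature_tables: dict[Task, pd.DataFrame] = {}
        anova_tables: dict[Task, pd.DataFrame] = {}
        ml_tables: dict[Task, pd.DataFrame] = {}
        for task in tasks:
            filtered, report = exclude_outliers(self.cohort, task)
            exclusions[task] = report
            feats = featurize_cohort(filtered, task, dt=cfg.dt_ms)
            feature_tables[task] = feats
            anova_tables[task] = anova_table_for_task(
                feats, task, alpha=cfg.analysis.alpha
            )
            if cfg.analysis.run_ml and not feats.empty:
                grids = [
                    run_model_grid(
                        feats,
                        task.value,
                        target=target,
                        n_perm=cfg.analysis.n_perm,
                        k=cfg.analysis.cv_folds,
                        seed=cfg.seed,
                    )
                    for target in cfg.analysis.targets
                ]
                ml_tables[task] = pd.concat(grids, ignore_index=True)
        manipulation = manipulation_check(self.cohort, alpha=cfg.analysis.alpha)
        return StudyResults(
            config=cfg,
            exclusions=exclusions,
            feature_tables=feature_tables,
            anova_tables=anova_tables,
            manipulation=manipulation,
            ml_tables=ml_tables,
        )


def run_full_analysis(cfg: PipelineConfig) -> StudyResults:
    """Simulate, analyse and write every report under ``cfg.outdir``."""
    study = StressStudy.from_simulation(cfg)
    results = study.fit()
    results.save(cfg.outdir)
    return results


def run_task_separability_probe(
    cohort: CohortDataset, seed: int = 0, k: int = 5
) -> float:
    """Feasibility check: classify point-and-click vs drag-and-drop.

    Uses only the 13 features shared by both tasks, application-stage
    sessions, the RBF-SVM specification and stratified five-fold CV;
    the two tasks' kinematics differ so strongly that accuracy should be
    at ceiling on any reasonable cohort.
    """
    frames = []
    for task in (Task.POINT_AND_CLICK, Task.DRAG_AND_DROP):
        feats = featurize_cohort(cohort, task)
        feats = feats[feats["stage"] == "application"]
        frames.append(feats[["pid", "task", *COMMON_FEATURES]])
    table = pd.concat(frames, ignore_index=True)
    X = table[list(COMMON_FEATURES)].to_numpy(dtype=float)
    y = table["task"].to_numpy()
    res = fit_predict_cv(X, y, ModelSpec("rbf_svm_classifier"), k=k, seed=seed)
    return res.mean_score
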