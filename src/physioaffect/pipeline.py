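"""End-to-end orchestration: simulate -> preprocess/extract -> reduce ->
screen -> classify -> report, with a serialisable configuration and a run
manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as paio
from .classification import (
    TASK_FACTORIES,
    classify_task,
    rank_selected_features,
    split_subgroups,
)
from .exceptions import ConfigurationError
from .features import build_feature_matrix
from .reduction import CorrelationThresholdReducer
from .screening import DEFAULT_VARIABLES, screen_variables
from .synth import StudyDesign, simulate_cohort

logger = logging.getLogger("physioaffect")


@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=lambda: StudyDesign(n_subjects=12))
    baseline_window: float = 2.0
    amp_threshold: float = 0.05
    reduction_threshold: float = 0.95
    screening_variables: tuple = DEFAULT_VARIABLES
    family_alpha: float = 0.05
    tasks: tuple = ("valence3", "affect5")
    subgroups: tuple = ("all", "female", "male")
    age_cutoff: float = 45.0
    selection_methods: tuple = ("forward", "backward")
    inner_cv: int | None = 3
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    write_signals: bool = False

    def validate(self) -> None:
        self.design.validate()
        if not 0.0 < self.reduction_threshold <= 1.0:
            raise ConfigurationError(
                f"reduction_threshold must be in (0, 1], got {self.reduction_threshold}"
            )
        if not 0.0 < self.family_alpha < 1.0:
            raise ConfigurationError("family_alpha must be in (0, 1)")
        unknown = [t for t in self.tasks if t not in TASK_FACTORIES]
        if unknown:
            raise ConfigurationError(f"unknown tasks: {unknown}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_json_default)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "design" in data and isinstance(data["design"], dict):
            design = dict(data["design"])
            if "effect_params" in design and isinstance(design["effect_params"], dict):
                from .synth import EffectParams

                design["effect_params"] = EffectParams(**design["effect_params"])
            if "age_range" in design:
                design["age_range"] = tuple(design["age_range"])
            data["design"] = StudyDesign(**design)
        for key in ("screening_variables", "tasks", "subgroups", "selection_methods"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every configured stage, writing artifacts into ``outdir``.

    Returns a dict of artifact paths plus in-memory stage outputs.  Re-runs
    with an unchanged config produce byte-identical CSV/JSON artifacts.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_path = outdir / "run.log"
    results: dict = {"outdir": outdir, "config_hash": chash}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.time()

    def done(name, t0, **counts):
        line = f"{name}\t{time.time() - t0:.2f}s\t" + "\t".join(
            f"{k}={v}" for k, v in counts.items()
        )
        logger.info("stage %s done: %s", name, counts)
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    # --- simulate
    t0 = stage("simulate")
    profiles, timeline, recordings = simulate_cohort(config.design)
    paio.write_profiles(profiles, outdir / "profiles.csv")
    events_dir = outdir / "events"
    events_dir.mkdir(exist_ok=True)
    paio.write_timeline(timeline, events_dir / "session_events.tsv")
    if config.write_signals:
        sig_dir = outdir / "signals"
        for rec in recordings:
            paio.write_recording(rec, sig_dir)
    done("simulate", t0, subjects=len(profiles), blocks=len(timeline.blocks))

    # --- extract
    t0 = stage("extract")
    matrix = build_feature_matrix(
        recordings,
        timeline,
        baseline_window=config.baseline_window,
        amp_threshold=config.amp_threshold,
    )
    paio.write_feature_matrix(matrix, outdir / "features_raw.csv")
    done("extract", t0, rows=len(matrix))

    # --- reduce
    t0 = stage("reduce")
    reducer = CorrelationThresholdReducer(threshold=config.reduction_threshold).fit(matrix)
    reduced = reducer.transform(matrix)
    paio.write_feature_matrix(reduced, outdir / "features_reduced.csv")
    with open(outdir / "reduction.json", "w") as fh:
        json.dump(reducer.report_.to_dict(), fh, indent=2, sort_keys=True)
    done("reduce", t0, retained=len(reducer.retained_), removed=len(reducer.removed_))

    # --- screen
    t0 = stage("screen")
    screening = screen_variables(
        matrix, profiles, variables=config.screening_variables, family_alpha=config.family_alpha
    )
    screening.to_csv(outdir / "screening.csv", index=False)
    done("screen", t0, rows=len(screening), significant=int(screening["significant"].sum()))
    results.update(
        profiles=profiles, timeline=timeline, matrix=matrix, reduced=reduced, screening=screening
    )

    # --- classify
    if config.tasks:
        t0 = stage("classify")
        cls_dir = outdir / "classification"
        cls_dir.mkdir(exist_ok=True)
        subgroups = {
            sg.name: sg for sg in split_subgroups(profiles, age_cutoff=config.age_cutoff)
        }
        task_results = []
        for sg_name in config.subgroups:
            sg = subgroups[sg_name]
            if not sg.subject_ids:
                continue
            for task_name in config.tasks:
                res = classify_task(
                    reduced,
                    sg,
                    TASK_FACTORIES[task_name](),
                    selection_methods=config.selection_methods,
                    inner_cv=config.inner_cv,
                    C=config.svm_C,
                    gamma=config.svm_gamma,
                )
                task_results.append(res)
                with open(cls_dir / f"{sg_name}_{task_name}.json", "w") as fh:
                    json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
        ranking, shares = rank_selected_features(task_results)
        ranking.to_csv(outdir / "ranking.csv", index=False)
        shares.to_csv(outdir / "signal_shares.csv", index=False)
        results.update(task_results=task_results, ranking=ranking, shares=shares)
        done("classify", t0, runs=len(task_results))

    manifest = {
        "config_hash": chash,
        "seed": config.design.seed,
        "config": config.to_dict(),
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return results


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "physioaffect": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
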