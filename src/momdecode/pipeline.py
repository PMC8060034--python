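"""End-to-end orchestration: configuration, staged runs, manifests.

A :class:`RunConfig` bundles the task, behaviour and sensor models with the
analysis parameters; :func:`run` executes the enabled stages in dependency
order for a cohort of simulated subjects and writes tidy CSV/JSON artefacts
plus a manifest with content hashes.  Identical config + master seed
reproduce byte-identical CSV/JSON outputs.

Stages
------
``behaviour``     per-block miss rates and correct RTs per subject
``direction``     time-resolved left/right decoding per subject
``distance``      per-distance decoding accuracies for the 8 condition cells
``connectivity``  frontal-occipital informational connectivity per cell
``error``         correct-vs-miss generalization + single-trial Cohen's d
``prediction``    accumulated-accuracy LOSO outcome prediction
``stats``         Bayes-factor tables computed from the stage CSVs
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .bayes import bf_anova_effect, interpret_bf, jzs_bf_ttest
from .connectivity import connectivity_by_condition
from .decoding import CVScheme, decode_direction_timecourse, decode_distance_pairwise, per_distance_accuracy
from .epochs import EpochSet, bin_distances, default_sensor_groups, downsample, equalize_trial_counts, pool_directions
from .errors import (
    loso_predict,
    prepare_prediction_data,
    single_trial_accuracy_distributions,
    train_correct_test_miss,
)
from .task import (
    BehaviourModel,
    SensorModel,
    TaskConfig,
    generate_schedule,
    simulate_behaviour,
    simulate_epochs,
    summarize_behaviour,
)

__all__ = ["RunConfig", "RunManifest", "run", "simulate_subject"]

ALL_STAGES = (
    "behaviour",
    "direction",
    "distance",
    "connectivity",
    "error",
    "prediction",
    "stats",
)

_TUPLE_FIELDS = {
    "onset_to_deflection_ms",
    "deflection_to_collision_ms",
    "total_motion_ms",
    "isi_ms",
    "frontal_group",
    "occipital_group",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    master_seed: int = 0
    n_subjects: int = 21
    task: TaskConfig = field(default_factory=TaskConfig)
    behaviour: BehaviourModel = field(default_factory=BehaviourModel)
    sensors: SensorModel = field(default_factory=SensorModel)
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "momdecode_out"
    analysis_fs_hz: float = 200.0
    samples_per_bin: int = 5
    shrinkage: float = 0.2
    n_folds: int = 10
    connectivity_reps: int = 100

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        neural = {"direction", "distance", "connectivity", "error", "prediction"}
        if "stats" in self.stages and not (set(self.stages) & (neural | {"behaviour"})):
            # stats can also run standalone on cached CSVs; tolerated.
            pass

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub_cls in (("task", TaskConfig), ("behaviour", BehaviourModel),
                             ("sensors", SensorModel)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f in list(sub):
                    if f in _TUPLE_FIELDS and isinstance(sub[f], list):
                        sub[f] = tuple(sub[f])
                d[key] = sub_cls(**sub)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_jsonable(self.to_dict()), f, sort_keys=True)


@dataclass
class RunManifest:
    """Record of a run: config snapshot, per-stage timings, output hashes."""

    config: dict
    version: str
    stage_seconds: dict
    outputs: dict  # filename -> sha256

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "config": _jsonable(self.config),
                    "version": self.version,
                    "stage_seconds": self.stage_seconds,
                    "outputs": self.outputs,
                },
                f,
                indent=2,
                sort_keys=True,
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_subject(config: RunConfig, subject: int):
    """Schedule + behaviour + epochs for one subject, seeded from the master."""
    schedule = generate_schedule(
        config.task, seed=derive_seed(config.master_seed, "schedule", subject)
    )
    schedule = simulate_behaviour(
        schedule, config.behaviour,
        seed=derive_seed(config.master_seed, "behaviour", subject),
    )
    sensors = dataclasses.replace(
        config.sensors, seed=derive_seed(config.master_seed, "patterns")
    )
    epochs = simulate_epochs(
        schedule, sensors, seed=derive_seed(config.master_seed, "epochs", subject)
    )
    epochs.subject_id = f"S{subject:02d}"
    return schedule, epochs


def _condition_cells(labels: pd.DataFrame) -> dict[str, np.ndarray]:
    cells = {}
    for att in (True, False):
        for cond in ("active", "monitoring"):
            for half in ("early", "late"):
                ok = (
                    (labels["attended"] == att)
                    & (labels["condition"] == cond)
                    & (labels["epoch_half"] == half)
                    & (labels["outcome"] != "miss")
                    & ~labels["outcome"].str.startswith("false_alarm")
                )
                cells[f"{'att' if att else 'unatt'}/{cond}/{half}"] = np.flatnonzero(
                    ok.to_numpy()
                )
    return cells


def run(config: RunConfig) -> RunManifest:
    """Execute the enabled stages and write artefacts + manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stages = set(config.stages)
    neural_needed = stages & {"direction", "distance", "connectivity", "error", "prediction"}

    behaviour_rows: list[pd.DataFrame] = []
    direction_rows: list[pd.DataFrame] = []
    distance_rows: list[pd.DataFrame] = []
    connectivity_rows: list[pd.DataFrame] = []
    error_rows: list[pd.DataFrame] = []
    single_trial_rows: list[dict] = []
    prediction_inputs = []

    t0 = time.perf_counter()
    if stages & ({"behaviour"} | neural_needed):
        for s in range(config.n_subjects):
            schedule, epochs = simulate_subject(config, s)
            sid = f"S{s:02d}"
            if "behaviour" in stages:
                summary = summarize_behaviour(schedule)
                summary.insert(0, "subject", sid)
                behaviour_rows.append(summary)
            if not neural_needed:
                continue
            if epochs.fs_hz != config.analysis_fs_hz:
                epochs = downsample(epochs, config.analysis_fs_hz)
            cv = CVScheme(
                n_folds=config.n_folds,
                seed=derive_seed(config.master_seed, "cv", s),
            )
            if "direction" in stages:
                res = decode_direction_timecourse(epochs, cv=cv, shrinkage=config.shrinkage)
                direction_rows.append(
                    pd.DataFrame(
                        {
                            "subject": sid,
                            "time_ms": res.time_ms,
                            "accuracy": res.accuracy,
                        }
                    )
                )
            if stages & {"distance", "connectivity", "error", "prediction"}:
                binned = pool_directions(
                    bin_distances(epochs, samples_per_bin=config.samples_per_bin)
                )
            if "distance" in stages:
                cells = _condition_cells(binned.labels)
                eq = equalize_trial_counts(
                    cells, seed=derive_seed(config.master_seed, "eq", s)
                )
                for name, idx in eq.items():
                    att, cond, half = name.split("/")
                    cell_cv = CVScheme(
                        n_folds=min(config.n_folds, idx.size), seed=cv.seed
                    )
                    rdm = decode_distance_pairwise(
                        binned.select(idx), cv=cell_cv, shrinkage=config.shrinkage
                    )
                    acc = per_distance_accuracy(rdm)
                    distance_rows.append(
                        pd.DataFrame(
                            {
                                "subject": sid,
                                "attention": att,
                                "target_frequency": cond,
                                "epoch_half": half,
                                "distance": np.arange(1, acc.size + 1),
                                "accuracy": acc,
                            }
                        )
                    )
            if "connectivity" in stages:
                groups = default_sensor_groups(binned.n_sensors)
                tab = connectivity_by_condition(
                    binned,
                    groups,
                    cv=CVScheme(n_folds=min(config.n_folds, 5), seed=cv.seed),
                    shrinkage=config.shrinkage,
                    seed=derive_seed(config.master_seed, "conn", s),
                )
                tab.insert(0, "subject", sid)
                connectivity_rows.append(tab)
            if "error" in stages:
                gen = train_correct_test_miss(
                    binned,
                    shrinkage=config.shrinkage,
                    seed=derive_seed(config.master_seed, "error", s),
                )
                acc_c, acc_m = gen.per_distance()
                error_rows.append(
                    pd.DataFrame(
                        {
                            "subject": sid,
                            "distance": np.arange(1, acc_c.size + 1),
                            "accuracy_correct": acc_c,
                            "accuracy_miss": acc_m,
                        }
                    )
                )
                dist = single_trial_accuracy_distributions(
                    gen.correct_trial_acc, gen.miss_trial_acc
                )
                single_trial_rows.append(
                    {
                        "subject": sid,
                        "mean_correct": float(np.mean(dist.correct)),
                        "mean_miss": float(np.mean(dist.miss)),
                        "cohens_d": dist.cohens_d,
                        "n_correct": int(dist.correct.size),
                        "n_miss": int(dist.miss.size),
                    }
                )
            if "prediction" in stages:
                prediction_inputs.append(
                    prepare_prediction_data(
                        binned,
                        seed=derive_seed(config.master_seed, "predict", s),
                        shrinkage=config.shrinkage,
                    )
                )
    timings["simulate+decode"] = time.perf_counter() - t0

    outputs: dict[str, str] = {}

    def write_csv(name: str, frames) -> None:
        if isinstance(frames, list):
            if not frames:
                return
            df = pd.concat(frames, ignore_index=True)
        else:
            df = frames
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        outputs[name] = _sha256(path)

    write_csv("behaviour_summary.csv", behaviour_rows)
    write_csv("direction_decoding.csv", direction_rows)
    write_csv("distance_decoding.csv", distance_rows)
    write_csv("connectivity.csv", connectivity_rows)
    write_csv("error_generalization.csv", error_rows)
    if single_trial_rows:
        write_csv("error_single_trial.csv", pd.DataFrame(single_trial_rows))

    if "prediction" in stages and prediction_inputs:
        t0 = time.perf_counter()
        results = loso_predict(prediction_inputs)
        pred_rows = []
        for res in results:
            for d, acc in enumerate(res.accuracy_by_distance, start=1):
                pred_rows.append(
                    {
                        "subject": f"S{res.subject:02d}",
                        "distance": d,
                        "accuracy": acc,
                        "chosen_m": res.chosen_m,
                    }
                )
        write_csv("prediction.csv", pd.DataFrame(pred_rows))
        timings["prediction"] = time.perf_counter() - t0

    if "stats" in stages:
        t0 = time.perf_counter()
        stats_frames = _stats_stage(out, config)
        for name, df in stats_frames.items():
            write_csv(name, df)
        timings["stats"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=config.to_dict(),
        version=_version(),
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        outputs=outputs,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__

    return __version__


def _stats_stage(out: Path, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Bayes-factor tables from the stage CSVs present in ``out``."""
    frames: dict[str, pd.DataFrame] = {}
    seed = derive_seed(config.master_seed, "stats")
    beh_path = out / "behaviour_summary.csv"
    if beh_path.exists():
        beh = pd.read_csv(beh_path)
        rows = []
        for b, g in beh.groupby("block_in_condition"):
            piv = g.pivot_table(index="subject", columns="condition", values="miss_rate")
            if {"active", "monitoring"} <= set(piv.columns) and len(piv) >= 2:
                try:
                    bf = jzs_bf_ttest(
                        piv["monitoring"].to_numpy(), piv["active"].to_numpy(),
                        paired=True,
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "effect": "miss_rate_monitoring_vs_active",
                        "location": int(b),
                        "bf10": bf,
                        "category": interpret_bf(bf),
                    }
                )
        if rows:
            frames["stats_behaviour.csv"] = pd.DataFrame(rows)
    dist_path = out / "distance_decoding.csv"
    if dist_path.exists():
        dist = pd.read_csv(dist_path)
        mean_tab = (
            dist.groupby(["subject", "attention", "target_frequency", "epoch_half"])[
                "accuracy"
            ]
            .mean()
            .reset_index()
            .rename(columns={"accuracy": "value"})
        )
        rows = []
        for effect in (
            "attention",
            "target_frequency",
            "epoch_half",
            "target_frequency:epoch_half",
        ):
            res = bf_anova_effect(
                mean_tab,
                effect,
                factors=["attention", "target_frequency", "epoch_half"],
                seed=seed,
            )
            rows.append(
                {
                    "effect": res.effect,
                    "location": "mean_over_distances",
                    "bf10": res.bf10,
                    "category": res.category,
                }
            )
        frames["stats_distance.csv"] = pd.DataFrame(rows)
    conn_path = out / "connectivity.csv"
    if conn_path.exists():
        conn = pd.read_csv(conn_path)
        conn = conn[conn["outcome"] == "correct"].rename(columns={"rho": "value"})
        rows = []
        for effect in ("attention", "target_frequency", "epoch_half"):
            res = bf_anova_effect(
                conn[["subject", "attention", "target_frequency", "epoch_half", "value"]],
                effect,
                factors=["attention", "target_frequency", "epoch_half"],
                seed=seed,
            )
            rows.append(
                {
                    "effect": res.effect,
                    "location": "connectivity",
                    "bf10": res.bf10,
                    "category": res.category,
                }
            )
        frames["stats_connectivity.csv"] = pd.DataFrame(rows)
    pred_path = out / "prediction.csv"
    if pred_path.exists():
        pred = pd.read_csv(pred_path)
        rows = []
        for d, g in pred.groupby("distance"):
            try:
                bf = jzs_bf_ttest(g["accuracy"].to_numpy(), mu0=0.5)
            except ValueError:
                continue
            rows.append(
                {
                    "effect": "prediction_vs_chance",
                    "location": int(d),
                    "bf10": bf,
                    "category": interpret_bf(bf),
                }
            )
        if rows:
            frames["stats_prediction.csv"] = pd.DataFrame(rows)
    return frames
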