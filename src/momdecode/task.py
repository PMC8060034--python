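"""Multiple-object monitoring (MOM) task simulation.

The MOM paradigm presents moving dots travelling on visible trajectories
from two screen corners towards a central object.  Non-target dots deflect
automatically at a fixed deflection point; target dots (in the cued colour)
keep going and must be deflected by a button press before "collision".
Target frequency defines the two conditions: Active blocks have 16 targets
among the 32 cued-colour dots, Monitoring blocks only 2, which makes
Monitoring a classic vigilance setting in which miss rates climb with time
on task.

This module generates three layers of synthetic data:

1. :func:`generate_schedule` — the dot-by-dot block schedule with the
   published counts and timing statistics (64 dots per 110-s block, 32 per
   colour, onset-to-deflection 1226 +- 10 ms, deflection-to-collision
   410 +- 10 ms, inter-onset interval 1660 +- 890 ms),
2. :func:`simulate_behaviour` — hit/miss outcomes and reaction times from a
   configurable behaviour model with a vigilance decrement (miss probability
   grows with block index under Monitoring, falls to a plateau under
   Active),
3. :func:`simulate_epochs` — per-dot multi-sensor epochs whose signal
   carries direction-of-approach and distance-to-object information,
   amplified by attention on cued-colour trials and attenuated on miss
   trials.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "MIN_ISI_MS",
    "TaskConfig",
    "DotTrial",
    "BehaviourModel",
    "SensorModel",
    "SchedulingError",
    "generate_schedule",
    "simulate_behaviour",
    "simulate_epochs",
    "summarize_behaviour",
    "schedule_to_frame",
    "epoch_half_of_block",
]

#: Minimum inter-onset interval when drawing the schedule, milliseconds.
MIN_ISI_MS = 100.0


class SchedulingError(ValueError):
    """Raised when a configuration's dots cannot fit its block duration."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the MOM task (defaults follow the published design)."""

    block_duration_s: float = 110.0
    dots_per_block: int = 64
    dots_per_colour: int = 32
    targets_active: int = 16
    targets_monitoring: int = 2
    n_blocks_per_condition: int = 15
    practice_blocks: int = 2  # bookkeeping only; practice is excluded from analysis
    onset_to_deflection_ms: tuple[float, float] = (1226.0, 10.0)
    deflection_to_collision_ms: tuple[float, float] = (410.0, 10.0)
    total_motion_ms: tuple[float, float] = (2005.0, 12.0)
    isi_ms: tuple[float, float] = (1660.0, 890.0)
    condition_order: str = "active_first"

    def __post_init__(self) -> None:
        if self.dots_per_colour * 2 != self.dots_per_block:
            raise ValueError("dots_per_colour x 2 must equal dots_per_block")
        if not (0 <= self.targets_monitoring <= self.targets_active <= self.dots_per_colour):
            raise ValueError(
                "need targets_monitoring <= targets_active <= dots_per_colour"
            )
        for name in ("onset_to_deflection_ms", "deflection_to_collision_ms",
                     "total_motion_ms", "isi_ms"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} must have positive mean and sd >= 0")
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be positive")
        if self.condition_order not in ("active_first", "monitoring_first"):
            raise ValueError("condition_order must be active_first or monitoring_first")

    @property
    def n_blocks_total(self) -> int:
        return 2 * self.n_blocks_per_condition

    def block_condition(self, block_index: int) -> str:
        """Condition of main-experiment block ``block_index`` (0-based)."""
        first, second = (
            ("active", "monitoring")
            if self.condition_order == "active_first"
            else ("monitoring", "active")
        )
        return first if block_index < self.n_blocks_per_condition else second


@dataclass(frozen=True)
class DotTrial:
    """One moving dot: schedule entry plus (after simulation) its outcome."""

    trial_id: int
    block_index: int  # 0-based across the main experiment
    block_in_condition: int  # 1-based within its condition
    condition: str  # "active" | "monitoring"
    onset_ms: float  # from block start
    colour: str  # "cued" | "noncued"
    direction: str  # "left" | "right"
    role: str  # "target" | "event" | "distractor_event"
    deflection_ms: float  # from dot onset
    collision_ms: float  # from dot onset
    outcome: str = "none"
    rt_ms: float = float("nan")  # from deflection, defined iff a press is attributed

    def __post_init__(self) -> None:
        if not self.deflection_ms < self.collision_ms:
            raise ValueError("deflection must precede collision")


@dataclass(frozen=True)
class BehaviourModel:
    """Outcome model for cued targets and false alarms.

    Miss probability in block *b* (1-based within condition):

    * Active:      ``max(active_floor, base_miss_prob - active_learning_slope*(b-1))``
    * Monitoring:  ``clip(base_miss_prob + monitoring_extra_miss + vigilance_slope*(b-1), 0, 1)``

    Defaults are calibrated to the canonical vigilance-decrement pattern:
    block-1 miss rates near 29% (Active) and 40% (Monitoring), an Active
    plateau near 17% after five blocks, and Monitoring misses climbing
    towards ~76% by block 15.  Hit RTs are truncated-normal within the
    deflection-to-collision window, drifting slower under Monitoring and
    faster under Active as blocks pass.
    """

    base_miss_prob: float = 0.29
    monitoring_extra_miss: float = 0.11
    vigilance_slope: float = 0.026
    active_learning_slope: float = 0.03
    active_floor: float = 0.17
    rt_mean_ms: float = 280.0
    rt_sd_ms: float = 60.0
    rt_trend_active_ms: float = -3.0
    rt_trend_monitoring_ms: float = 4.0
    fa_rate: float = 0.035

    def __post_init__(self) -> None:
        for name in ("base_miss_prob", "fa_rate", "active_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.rt_sd_ms < 0:
            raise ValueError("rt_sd_ms must be non-negative")

    def miss_prob(self, condition: str, block_in_condition: int) -> float:
        b = block_in_condition - 1
        if condition == "active":
            p = max(self.active_floor, self.base_miss_prob - self.active_learning_slope * b)
        else:
            p = self.base_miss_prob + self.monitoring_extra_miss + self.vigilance_slope * b
        return float(np.clip(p, 0.0, 1.0))


@dataclass(frozen=True)
class SensorModel:
    """Generative model of the multi-sensor epochs.

    Each epoch spans -100..3000 ms around dot onset.  The signal is

    ``gain(colour) * (a_trial * dir_amp * pattern_dir + dist_scale * dist_amp
    * pattern_dist(bin(t))) * envelope(t) + noise``

    where ``envelope`` is a box-car from 100 ms post-onset to the deflection
    point with 20-ms half-cosine ramps, ``pattern_dist`` steps through 15
    smoothly varying sensor patterns as the dot's ordinal distance bin
    changes, ``gain`` is ``attention_gain`` on cued-colour trials and 1
    otherwise, ``dist_scale`` is ``miss_attenuation`` on miss trials and 1
    otherwise, and the per-trial direction amplitude ``a_trial`` has its
    variability inflated by ``miss_direction_noise_inflation`` on miss
    trials.  Amplitudes are calibrated so that at the default 160-sensor
    model single-trial mean distance-decoding accuracies centre near 0.60 on
    correct and 0.56 on miss trials.
    """

    n_sensors: int = 160
    fs_hz: float = 1000.0
    frontal_group: tuple[int, ...] | None = None
    occipital_group: tuple[int, ...] | None = None
    attention_gain: float = 1.6
    miss_attenuation: float = 0.6
    miss_direction_noise_inflation: float = 2.5
    noise_sd: float = 1.0
    direction_amp: float = 0.4
    distance_amp: float = 0.25
    trial_amp_jitter_sd: float = 0.25
    frontal_distance_gain: float = 1.0
    ramp_ms: float = 20.0
    signal_onset_ms: float = 100.0
    n_distance_bins: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention_gain < 0 or self.noise_sd < 0:
            raise ValueError("attention_gain and noise_sd must be >= 0")
        if not 0.0 <= self.miss_attenuation <= 1.0:
            raise ValueError("miss_attenuation must be in [0, 1]")
        if self.miss_direction_noise_inflation < 1.0:
            raise ValueError("miss_direction_noise_inflation must be >= 1")
        fro, occ = self.sensor_groups()
        if set(fro) & set(occ):
            raise ValueError("frontal and occipital groups must be disjoint")
        for idx in (*fro, *occ):
            if not 0 <= idx < self.n_sensors:
                raise ValueError("sensor group index out of range")

    def sensor_groups(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """(frontal, occipital) index tuples; quartile defaults if unset."""
        q = max(1, self.n_sensors // 4)
        fro = self.frontal_group if self.frontal_group is not None else tuple(range(q))
        occ = (
            self.occipital_group
            if self.occipital_group is not None
            else tuple(range(self.n_sensors - q, self.n_sensors))
        )
        return tuple(fro), tuple(occ)

    def spatial_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Draw (direction_pattern, distance_patterns) from the model seed.

        The direction pattern is a fixed random unit vector.  The 15
        distance patterns trace a quarter great-circle between two random
        orthonormal vectors, so neighbouring bins have similar patterns and
        pattern separation grows with ordinal distance.  Patterns are
        indexed by distance (row 0 = distance 1, nearest).
        """
        rng = np.random.default_rng(self.seed)
        dir_pat = rng.standard_normal(self.n_sensors)
        dir_pat /= np.linalg.norm(dir_pat)
        u = rng.standard_normal(self.n_sensors)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(self.n_sensors)
        v -= u @ v * u
        v /= np.linalg.norm(v)
        theta = np.linspace(0.0, np.pi / 2.0, self.n_distance_bins)
        pats = np.cos(theta)[:, None] * u[None, :] + np.sin(theta)[:, None] * v[None, :]
        if self.frontal_distance_gain != 1.0:
            fro, _ = self.sensor_groups()
            pats = pats.copy()
            pats[:, list(fro)] *= self.frontal_distance_gain
        return dir_pat, pats


def epoch_half_of_block(block_in_condition: int, n_blocks_per_condition: int) -> str:
    """Early/late (time-on-task) label of a block within its condition.

    With the canonical 15 blocks per condition, blocks 1-5 are ``early`` and
    11-15 are ``late``; for other counts the first and last
    ``min(5, n_blocks // 3)`` blocks are used (at least one each).
    """
    k = max(1, min(5, n_blocks_per_condition // 3)) if n_blocks_per_condition > 1 else 1
    if block_in_condition <= k:
        return "early"
    if block_in_condition > n_blocks_per_condition - k:
        return "late"
    return "mid"


def generate_schedule(config: TaskConfig, seed: int) -> list[DotTrial]:
    """Generate the dot schedule for the 2 x n_blocks_per_condition main blocks.

    Per block: exactly ``dots_per_block`` dots, half per colour; the
    condition's target count among cued dots and the same count of
    distractor events among non-cued dots; onsets drawn from the truncated
    ISI distribution (minimum 100 ms) and rescaled linearly so every dot
    starts (and nominally finishes moving) within the block; directions
    split evenly between the two entry corners; timing landmarks drawn
    per-dot from the configured mean +- sd.
    """
    block_ms = config.block_duration_s * 1000.0
    if (config.dots_per_block - 1) * MIN_ISI_MS > block_ms:
        raise SchedulingError(
            f"{config.dots_per_block} dots cannot fit a "
            f"{config.block_duration_s}-s block at the minimum "
            f"{MIN_ISI_MS:.0f}-ms inter-onset interval"
        )
    rng = np.random.default_rng(seed)
    isi_mean, isi_sd = config.isi_ms
    d2d_mean, d2d_sd = config.onset_to_deflection_ms
    d2c_mean, d2c_sd = config.deflection_to_collision_ms
    trials: list[DotTrial] = []
    trial_id = 0
    for block in range(config.n_blocks_total):
        condition = config.block_condition(block)
        block_in_cond = block % config.n_blocks_per_condition + 1
        n = config.dots_per_block
        # onsets: truncated-normal ISIs, then a linear rescale into the block
        isis = np.maximum(rng.normal(isi_mean, isi_sd, size=n - 1), MIN_ISI_MS)
        onsets = np.concatenate([[0.0], np.cumsum(isis)])
        span = block_ms - config.total_motion_ms[0]
        span = max(span, (n - 1) * MIN_ISI_MS)
        if onsets[-1] > 0:
            onsets = onsets * (span / onsets[-1])
        half = config.dots_per_colour
        colours = np.array(["cued"] * half + ["noncued"] * half)
        rng.shuffle(colours)
        directions = np.array(["left", "right"] * (n // 2) + ["left"] * (n % 2))
        rng.shuffle(directions)
        n_targets = (
            config.targets_active if condition == "active" else config.targets_monitoring
        )
        roles = np.array(["event"] * n, dtype=object)
        cued_idx = np.flatnonzero(colours == "cued")
        noncued_idx = np.flatnonzero(colours == "noncued")
        roles[rng.choice(cued_idx, size=n_targets, replace=False)] = "target"
        roles[rng.choice(noncued_idx, size=n_targets, replace=False)] = "distractor_event"
        defl = np.maximum(rng.normal(d2d_mean, d2d_sd, size=n), 1.0)
        d2c = np.maximum(rng.normal(d2c_mean, d2c_sd, size=n), 1.0)
        for i in range(n):
            trials.append(
                DotTrial(
                    trial_id=trial_id,
                    block_index=block,
                    block_in_condition=block_in_cond,
                    condition=condition,
                    onset_ms=float(onsets[i]),
                    colour=str(colours[i]),
                    direction=str(directions[i]),
                    role=str(roles[i]),
                    deflection_ms=float(defl[i]),
                    collision_ms=float(defl[i] + d2c[i]),
                )
            )
            trial_id += 1
    return trials


def simulate_behaviour(
    schedule: list[DotTrial], model: BehaviourModel, seed: int
) -> list[DotTrial]:
    """Fill outcomes and reaction times for a generated schedule.

    Cued targets become hits with probability ``1 - p(block, condition)``;
    hits receive truncated-normal RTs within the deflection-to-collision
    window.  Non-target dots trigger false alarms at ``fa_rate`` (cued
    events split between early and at-event presses; non-cued dots give
    wrong-colour presses).  Presses are generated per dot, so attribution of
    a press to the dot nearest the central object is exact by construction.
    """
    rng = np.random.default_rng(seed)
    out: list[DotTrial] = []
    for dot in schedule:
        outcome, rt = "none", float("nan")
        if dot.role == "target" and dot.colour == "cued":
            p_miss = model.miss_prob(dot.condition, dot.block_in_condition)
            if rng.random() < p_miss:
                outcome = "miss"
            else:
                outcome = "hit"
                trend = (
                    model.rt_trend_active_ms
                    if dot.condition == "active"
                    else model.rt_trend_monitoring_ms
                )
                mean = model.rt_mean_ms + trend * (dot.block_in_condition - 1)
                window = dot.collision_ms - dot.deflection_ms
                for _ in range(1000):
                    draw = rng.normal(mean, model.rt_sd_ms)
                    if 0.0 < draw <= window:
                        rt = float(draw)
                        break
                else:  # pathological model: fall back to the window midpoint
                    rt = float(window / 2.0)
        elif dot.colour == "cued":
            if rng.random() < model.fa_rate:
                outcome = "false_alarm_early" if rng.random() < 0.5 else "false_alarm_event"
            else:
                outcome = "correct_reject"
        else:
            if rng.random() < model.fa_rate:
                outcome = "false_alarm_wrong_colour"
        out.append(dataclasses.replace(dot, outcome=outcome, rt_ms=rt))
    return out


def schedule_to_frame(schedule: list[DotTrial]) -> pd.DataFrame:
    """Schedule (with or without outcomes) as a tidy per-trial table."""
    return pd.DataFrame([dataclasses.asdict(d) for d in schedule])


def summarize_behaviour(schedule: list[DotTrial]) -> pd.DataFrame:
    """Per-block behavioural summary: miss rate over targets and correct RT.

    ``miss_rate`` is misses / targets within the block and is NaN (flagged
    by ``n_targets == 0``), never zero, for blocks without targets; RT is
    averaged over hits only.
    """
    df = schedule_to_frame(schedule)
    rows = []
    for (block, cond, bic), g in df.groupby(
        ["block_index", "condition", "block_in_condition"], sort=True
    ):
        targets = g[(g["role"] == "target") & (g["colour"] == "cued")]
        n_targets = len(targets)
        n_miss = int((targets["outcome"] == "miss").sum())
        hits = targets[targets["outcome"] == "hit"]
        rows.append(
            {
                "block": block,
                "block_in_condition": bic,
                "condition": cond,
                "n_targets": n_targets,
                "n_miss": n_miss,
                "miss_rate": (n_miss / n_targets) if n_targets else float("nan"),
                "mean_correct_rt_ms": float(hits["rt_ms"].mean()) if len(hits) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def simulate_epochs(
    schedule: list[DotTrial],
    sensor_model: SensorModel,
    seed: int,
    tmin_ms: float = -100.0,
    tmax_ms: float = 3000.0,
) -> EpochSet:
    """Generate one multi-sensor epoch per dot (outcomes must be filled).

    See :class:`SensorModel` for the signal equation.  Epochs are generated
    independently per dot even though real dots overlap on screen; the
    decoding pipeline analyses per-dot epochs the same way.
    """
    model = sensor_model
    rng = np.random.default_rng(seed)
    dir_pat, dist_pats = model.spatial_patterns()
    step = 1000.0 / model.fs_hz
    n_samp = int(round((tmax_ms - tmin_ms) / step)) + 1
    time_ms = tmin_ms + step * np.arange(n_samp)
    n_tr = len(schedule)
    data = np.empty((n_tr, model.n_sensors, n_samp), dtype=np.float32)
    nb = model.n_distance_bins
    for i, dot in enumerate(schedule):
        defl = dot.deflection_ms
        env = _envelope(time_ms, model.signal_onset_ms, defl, model.ramp_ms)
        # ordinal distance bin per sample (15 = just appeared .. 1 = nearest)
        in_span = (time_ms >= 0.0) & (time_ms < defl)
        window = np.minimum((time_ms[in_span] * nb / defl).astype(int), nb - 1)
        dist_idx = np.zeros(n_samp, dtype=int)
        dist_idx[in_span] = nb - 1 - window
        gain = model.attention_gain if dot.colour == "cued" else 1.0
        is_miss = dot.outcome == "miss"
        jitter_sd = model.trial_amp_jitter_sd * (
            model.miss_direction_noise_inflation if is_miss else 1.0
        )
        a_trial = 1.0 + jitter_sd * rng.standard_normal()
        dir_sign = 1.0 if dot.direction == "left" else -1.0
        dist_scale = model.miss_attenuation if is_miss else 1.0
        sig = (
            gain * a_trial * dir_sign * model.direction_amp * np.outer(dir_pat, env)
            + gain * dist_scale * model.distance_amp * dist_pats[dist_idx].T * env[None, :]
        )
        noise = rng.standard_normal((model.n_sensors, n_samp))
        data[i] = sig + model.noise_sd * noise
    labels = schedule_to_frame(schedule)
    n_per_cond = int(labels.groupby("condition")["block_in_condition"].max().max())
    labels["attended"] = labels["colour"] == "cued"
    labels["epoch_half"] = [
        epoch_half_of_block(b, n_per_cond) for b in labels["block_in_condition"]
    ]
    return EpochSet(
        data=data,
        time_ms=time_ms,
        fs_hz=model.fs_hz,
        labels=labels,
        subject_id="sim",
    )


def _envelope(
    time_ms: np.ndarray, onset_ms: float, offset_ms: float, ramp_ms: float
) -> np.ndarray:
    """Box-car from ``onset_ms`` to ``offset_ms`` with half-cosine ramps."""
    env = np.zeros_like(time_ms)
    rise = (time_ms >= onset_ms) & (time_ms < onset_ms + ramp_ms)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (time_ms[rise] - onset_ms) / ramp_ms))
    env[(time_ms >= onset_ms + ramp_ms) & (time_ms <= offset_ms - ramp_ms)] = 1.0
    fall = (time_ms > offset_ms - ramp_ms) & (time_ms <= offset_ms)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (offset_ms - time_ms[fall]) / ramp_ms))
    return env
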