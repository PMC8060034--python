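"""RDM-based informational connectivity between sensor groups.

Informational connectivity asks whether two sensor groups (here
peri-frontal and peri-occipital) carry a *similar structure* of distance
information, quantified as the Spearman rank correlation between the 105
lower-triangle entries of the two groups' 15 x 15 distance-decoding RDMs.
Being rank-based, the measure is invariant to any strictly increasing
transform of either RDM and therefore insensitive to overall decoding
level.

:func:`connectivity_by_condition` computes the measure for the eight
attention x target-frequency x time-on-task cells (trial counts equalized
across cells), and for the correct-vs-miss contrast where correct trials
are subsampled to the miss count and the subsampling repeated (100
repetitions by default) before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._seeds import derive_seed
from .decoding import CVScheme, RDM, decode_distance_pairwise
from .epochs import DistanceBinnedSet, SensorGroups, equalize_trial_counts

__all__ = [
    "ConnectivityResult",
    "group_rdm",
    "informational_connectivity",
    "connectivity_by_condition",
]


@dataclass
class ConnectivityResult:
    """Connectivity for one condition cell (mean over subsample repetitions)."""

    rho: float
    group_a: str
    group_b: str
    condition: dict
    n_subsample_reps: int
    per_rep_rhos: np.ndarray | None = None


def group_rdm(
    binned: DistanceBinnedSet,
    group: np.ndarray,
    cv: CVScheme = CVScheme(),
    shrinkage: float | str = 0.2,
) -> RDM:
    """Distance RDM restricted to one sensor group's features."""
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("sensor group is empty")
    return decode_distance_pairwise(binned, cv=cv, shrinkage=shrinkage, sensors=group)


def informational_connectivity(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman correlation of the two RDMs' 105 lower-triangle entries.

    Returns NaN (with a warning) if either triangle is constant, in which
    case the rank correlation is undefined.
    """
    a = rdm_a.lower_triangle()
    b = rdm_b.lower_triangle()
    if a.size != b.size:
        raise ValueError("RDMs must have matching sizes")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        warnings.warn("constant RDM triangle: informational connectivity undefined")
        return float("nan")
    rho, _ = scipy.stats.spearmanr(a, b)
    return float(rho)


def _condition_cells(labels: pd.DataFrame, correct_outcomes: tuple[str, ...]) -> dict:
    """The 8 attention x target-frequency x time-on-task cells (correct trials)."""
    cells = {}
    for att in (True, False):
        for cond in ("active", "monitoring"):
            for half in ("early", "late"):
                name = f"{'att' if att else 'unatt'}/{cond}/{half}"
                mask = (
                    (labels["attended"] == att)
                    & (labels["condition"] == cond)
                    & (labels["epoch_half"] == half)
                    & (
                        labels["outcome"].isin(correct_outcomes)
                        if att
                        else ~labels["outcome"].str.startswith("false_alarm")
                    )
                )
                cells[name] = np.flatnonzero(mask.to_numpy())
    return cells


def connectivity_by_condition(
    binned: DistanceBinnedSet,
    sensor_groups: SensorGroups,
    group_a: str = "frontal",
    group_b: str = "occipital",
    cv: CVScheme = CVScheme(),
    shrinkage: float | str = 0.2,
    outcome_contrast: bool = False,
    n_reps: int = 100,
    seed: int = 0,
    correct_outcomes: tuple[str, ...] = ("hit", "correct_reject"),
) -> pd.DataFrame:
    """Informational connectivity per condition cell.

    Without ``outcome_contrast``: the eight attention x target-frequency x
    time-on-task cells on correct trials, trial counts equalized across the
    eight cells by seeded subsampling (one repetition — the cells are
    equalized jointly, so a single subsample suffices and ``n_reps`` applies
    to the outcome contrast only).

    With ``outcome_contrast``: attended trials only, cells = target
    frequency x time-on-task x outcome (correct, miss); per cell the correct
    trials are subsampled to the miss count and the RDM correlation averaged
    over ``n_reps`` repetitions.  Raises a clear error when the miss cell is
    empty.
    """
    labels = binned.labels
    ga, gb = sensor_groups[group_a], sensor_groups[group_b]
    rows = []
    if not outcome_contrast:
        cells = _condition_cells(labels, correct_outcomes)
        for name, idx in cells.items():
            if idx.size == 0:
                raise ValueError(f"condition cell {name!r} has no trials")
        eq = equalize_trial_counts(cells, seed=derive_seed(seed, "cells"))
        for name, idx in eq.items():
            att, cond, half = name.split("/")
            sub = binned.select(idx)
            rho = informational_connectivity(
                group_rdm(sub, ga, cv=cv, shrinkage=shrinkage),
                group_rdm(sub, gb, cv=cv, shrinkage=shrinkage),
            )
            rows.append(
                {
                    "attention": att,
                    "target_frequency": cond,
                    "epoch_half": half,
                    "outcome": "correct",
                    "rho": rho,
                    "n_trials": idx.size,
                    "n_reps": 1,
                }
            )
        return pd.DataFrame(rows)

    att_labels = labels["attended"].to_numpy()
    n_miss_total = int(((labels["outcome"] == "miss") & att_labels).sum())
    if n_miss_total == 0:
        raise ValueError(
            "correct-vs-miss connectivity requires miss trials; none present"
        )
    for cond in ("active", "monitoring"):
        for half in ("early", "late"):
            base = (
                att_labels
                & (labels["condition"] == cond).to_numpy()
                & (labels["epoch_half"] == half).to_numpy()
            )
            miss_idx = np.flatnonzero(base & (labels["outcome"] == "miss").to_numpy())
            corr_idx = np.flatnonzero(
                base & labels["outcome"].isin(correct_outcomes).to_numpy()
            )
            cell = f"{cond}/{half}"
            if miss_idx.size == 0 or corr_idx.size == 0:
                raise ValueError(f"cell {cell!r} lacks correct or miss trials")
            n_cv = min(cv.n_folds, max(2, miss_idx.size))
            cv_cell = CVScheme(n_folds=min(n_cv, miss_idx.size), seed=cv.seed)
            rho_miss = informational_connectivity(
                group_rdm(binned.select(miss_idx), ga, cv=cv_cell, shrinkage=shrinkage),
                group_rdm(binned.select(miss_idx), gb, cv=cv_cell, shrinkage=shrinkage),
            )
            rows.append(
                {
                    "attention": "att",
                    "target_frequency": cond,
                    "epoch_half": half,
                    "outcome": "miss",
                    "rho": rho_miss,
                    "n_trials": miss_idx.size,
                    "n_reps": 1,
                }
            )
            per_rep = np.empty(n_reps)
            for rep in range(n_reps):
                rng = np.random.default_rng(derive_seed(seed, cell, rep))
                take = (
                    corr_idx
                    if corr_idx.size <= miss_idx.size
                    else np.sort(rng.choice(corr_idx, size=miss_idx.size, replace=False))
                )
                sub = binned.select(take)
                per_rep[rep] = informational_connectivity(
                    group_rdm(sub, ga, cv=cv_cell, shrinkage=shrinkage),
                    group_rdm(sub, gb, cv=cv_cell, shrinkage=shrinkage),
                )
            rows.append(
                {
                    "attention": "att",
                    "target_frequency": cond,
                    "epoch_half": half,
                    "outcome": "correct",
                    "rho": (
                        float(np.nanmean(per_rep))
                        if np.isfinite(per_rep).any()
                        else float("nan")
                    ),
                    "n_trials": miss_idx.size,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
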