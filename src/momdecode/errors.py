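"""Correct-vs-miss generalization and single-trial behavioural-error prediction.

The core idea: classifiers trained exclusively on *correct* trials probe
whether the same task-relevant information (the dot's ordinal distance to
the central object) is present on *miss* trials.  Three analyses build on
it:

* :func:`train_correct_test_miss` — cross-validated distance decoding where
  each held-out fold of correct trials is sized to roughly the miss count,
  and the same classifiers are tested on all miss trials;
* :func:`single_trial_accuracy_distributions` — per-trial mean classifier
  correctness, summarised as a correct-vs-miss Cohen's d;
* the accumulated-accuracy predictor (:func:`prepare_prediction_data`,
  :func:`sweep_thresholds`, :func:`loso_predict`) — a second-level
  classifier that labels an unseen trial *miss* when its running mean of
  first-level classifier correctness (accumulated from distance 15 down to
  the current distance) falls more than ``m`` validation standard
  deviations below the validation mean, with the multiplier ``m``
  transferred leave-one-subject-out.

The accumulation count obeys ``N(d) = C(15,2) - C(d-1,2)``: 14 classifiers
at distance 15, 27 at 14, ..., all 105 at distance 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .decoding import (
    CVScheme,
    DEFAULT_SHRINKAGE,
    N_DISTANCES,
    _fold_train_test,
    _shrunk_pooled_cov,
)
from .epochs import DistanceBinnedSet, EpochSet

__all__ = [
    "CORRECT_OUTCOMES",
    "GeneralizationResult",
    "SingleTrialDistributions",
    "PredictionData",
    "ThresholdSweep",
    "PredictionResult",
    "accumulation_count",
    "accumulate_accuracy",
    "train_correct_test_miss",
    "train_correct_test_miss_direction",
    "single_trial_accuracy_distributions",
    "split_correct_trials",
    "build_accumulation_traces",
    "prepare_prediction_data",
    "sweep_thresholds",
    "loso_predict",
    "default_m_grid",
]

#: Outcomes counted as behaviourally correct on attended trials.
CORRECT_OUTCOMES = ("hit", "correct_reject")


def default_m_grid() -> np.ndarray:
    """The threshold-multiple grid 0.1, 0.2, ..., 4.0."""
    return np.round(np.arange(0.1, 4.01, 0.1), 1)


def accumulation_count(d: int, n_distances: int = N_DISTANCES) -> int:
    """Number of classifier accuracies accumulated by distance ``d``.

    ``N(d) = C(n, 2) - C(d - 1, 2)``: every pair except those entirely
    nearer than ``d``.
    """
    if not 1 <= d <= n_distances:
        raise ValueError(f"distance must be in 1..{n_distances}")
    return comb(n_distances, 2) - comb(d - 1, 2)


def _pair_order(n_distances: int = N_DISTANCES) -> list[tuple[int, int]]:
    """Fixed (d_far, d_near) ordering of the pairwise classifiers."""
    return [
        (far, near)
        for far in range(2, n_distances + 1)
        for near in range(1, far)
    ]


def accumulate_accuracy(
    trial_flags: dict[tuple[int, int], float], d: int,
    n_distances: int = N_DISTANCES,
) -> tuple[float, int]:
    """Cumulative mean classifier correctness for one trial at distance ``d``.

    ``trial_flags`` maps each pair ``(d_far, d_near)`` to the 0/1
    correctness of that classifier for this trial (evaluated on the sample
    at the pair's farther distance, i.e. when the classifier joined the
    accumulation).  Includes every pair involving any distance >= ``d``.
    """
    keys = [(far, near) for far, near in _pair_order(n_distances) if far >= d]
    missing = [k for k in keys if k not in trial_flags]
    if missing:
        raise ValueError(f"missing classifier flags for pairs {missing[:3]}...")
    vals = [trial_flags[k] for k in keys]
    n = accumulation_count(d, n_distances)
    assert len(vals) == n
    return float(np.mean(vals)), n


@dataclass
class GeneralizationResult:
    """Distance decoding trained on correct trials, tested on correct and miss."""

    matrix_correct: np.ndarray  # (15, 15) accuracies on held-out correct trials
    matrix_miss: np.ndarray  # (15, 15) accuracies on miss trials
    correct_trial_acc: np.ndarray  # per-trial mean correctness, correct trials
    miss_trial_acc: np.ndarray  # per-trial mean correctness, miss trials
    correct_ids: np.ndarray
    miss_ids: np.ndarray
    n_folds: int

    def per_distance(self) -> tuple[np.ndarray, np.ndarray]:
        """(correct, miss) per-distance accuracy vectors (mean of 14 pairings)."""
        with np.errstate(invalid="ignore"):
            return (
                np.nanmean(self.matrix_correct, axis=1),
                np.nanmean(self.matrix_miss, axis=1),
            )


def _attended(binned: DistanceBinnedSet) -> DistanceBinnedSet:
    return binned.select(binned.labels["attended"].to_numpy().astype(bool))


def _outcome_indices(
    labels: pd.DataFrame, correct_outcomes: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    corr = np.flatnonzero(labels["outcome"].isin(correct_outcomes).to_numpy())
    miss = np.flatnonzero((labels["outcome"] == "miss").to_numpy())
    return corr, miss


def generalization_folds(n_correct: int, n_miss: int) -> int:
    """Fold count sized so each held-out correct fold ~ the miss count."""
    if n_miss == 0:
        raise ValueError("no miss trials: correct-vs-miss analysis undefined")
    return int(np.clip(round(n_correct / n_miss), 2, n_correct))


def train_correct_test_miss(
    binned: DistanceBinnedSet,
    shrinkage: float | str = DEFAULT_SHRINKAGE,
    seed: int = 0,
    correct_outcomes: tuple[str, ...] = CORRECT_OUTCOMES,
    miss_outcomes: tuple[str, ...] = ("miss",),
) -> GeneralizationResult:
    """Train distance classifiers on correct trials; test on correct and miss.

    Uses attended trials only (unattended dots have no behavioural
    outcome).  The number of folds is ``round(n_correct / n_miss)`` clamped
    to at least 2, so each held-out correct fold approximately matches the
    miss count; miss trials are tested by every fold's classifier and their
    flags averaged.  Only pre-deflection data enter by construction (the
    distance bins end at the deflection point).

    ``miss_outcomes`` may name false-alarm outcomes instead to run the same
    generalization for false alarms.
    """
    att = _attended(binned)
    corr_idx = np.flatnonzero(att.labels["outcome"].isin(correct_outcomes).to_numpy())
    miss_idx = np.flatnonzero(att.labels["outcome"].isin(miss_outcomes).to_numpy())
    if miss_idx.size == 0:
        raise ValueError(f"no trials with outcomes {miss_outcomes}")
    n_c, n_m = corr_idx.size, miss_idx.size
    n_folds = generalization_folds(n_c, n_m)
    feats = att.feature_matrix()
    n_bins = att.n_bins
    folds = CVScheme(n_folds=n_folds, seed=derive_seed(seed, "gen-folds")).assign(n_c)
    mat_c = np.full((n_bins, n_bins), np.nan)
    mat_m = np.full((n_bins, n_bins), np.nan)
    flags_c = np.zeros((n_c,))
    flags_m = np.zeros((n_m,))
    n_pairs = 0
    for i in range(1, n_bins):
        for j in range(i):
            Xf_c = feats[corr_idx, i].astype(float)
            Xn_c = feats[corr_idx, j].astype(float)
            Xf_m = feats[miss_idx, i].astype(float)
            Xn_m = feats[miss_idx, j].astype(float)
            pc = np.empty((n_c, 2))
            pm = np.zeros((n_m, 2))
            for f in range(n_folds):
                train, test = _fold_train_test(folds, f)
                Xtr = np.concatenate([Xf_c[train], Xn_c[train]])
                ytr = np.concatenate(
                    [np.ones(train.size, int), np.zeros(train.size, int)]
                )
                m0 = Xtr[ytr == 0].mean(axis=0)
                m1 = Xtr[ytr == 1].mean(axis=0)
                S_reg, _ = _shrunk_pooled_cov(Xtr, ytr, shrinkage)
                w = np.linalg.solve(S_reg, m1 - m0)
                cut = 0.5 * (m0 + m1) @ w
                pc[test, 0] = (Xf_c[test] @ w - cut > 0).astype(float)
                pc[test, 1] = (Xn_c[test] @ w - cut <= 0).astype(float)
                pm[:, 0] += (Xf_m @ w - cut > 0).astype(float)
                pm[:, 1] += (Xn_m @ w - cut <= 0).astype(float)
            pm /= n_folds
            mat_c[i, j] = mat_c[j, i] = pc.mean()
            mat_m[i, j] = mat_m[j, i] = pm.mean()
            flags_c += pc.mean(axis=1)
            flags_m += pm.mean(axis=1)
            n_pairs += 1
    flags_c /= n_pairs
    flags_m /= n_pairs
    ids = att.labels["trial_id"].to_numpy()
    return GeneralizationResult(
        matrix_correct=mat_c,
        matrix_miss=mat_m,
        correct_trial_acc=flags_c,
        miss_trial_acc=flags_m,
        correct_ids=ids[corr_idx],
        miss_ids=ids[miss_idx],
        n_folds=n_folds,
    )


def train_correct_test_miss_direction(
    epochs: EpochSet,
    shrinkage: float | str = DEFAULT_SHRINKAGE,
    seed: int = 0,
    correct_outcomes: tuple[str, ...] = CORRECT_OUTCOMES,
) -> dict:
    """Direction-of-approach generalization (correct-trained, miss-tested).

    Time-resolved left-vs-right decoding restricted to pre-deflection time
    points (after deflection the visual input differs between outcomes).
    Returns a dict with ``time_ms`` and accuracy traces for held-out
    correct and for miss trials.
    """
    labels = epochs.labels
    att = epochs.select(labels["attended"].to_numpy().astype(bool))
    corr_idx, miss_idx = _outcome_indices(att.labels, correct_outcomes)
    if miss_idx.size == 0:
        raise ValueError("no miss trials")
    t_keep = epochs.time_ms <= float(att.labels["deflection_ms"].min())
    y = (att.labels["direction"] == "right").to_numpy().astype(int)
    n_folds = generalization_folds(corr_idx.size, miss_idx.size)
    folds = CVScheme(n_folds=n_folds, seed=derive_seed(seed, "dir-folds")).assign(
        corr_idx.size
    )
    times = epochs.time_ms[t_keep]
    acc_c = np.empty(times.size)
    acc_m = np.empty(times.size)
    data = att.data[:, :, t_keep]
    for ti in range(times.size):
        Xc = data[corr_idx, :, ti].astype(float)
        Xm = data[miss_idx, :, ti].astype(float)
        fold_c = np.empty(n_folds)
        fold_m = np.empty(n_folds)
        for f in range(n_folds):
            train, test = _fold_train_test(folds, f)
            m0 = Xc[train][y[corr_idx][train] == 0].mean(axis=0)
            m1 = Xc[train][y[corr_idx][train] == 1].mean(axis=0)
            S_reg, _ = _shrunk_pooled_cov(Xc[train], y[corr_idx][train], shrinkage)
            w = np.linalg.solve(S_reg, m1 - m0)
            cut = 0.5 * (m0 + m1) @ w
            fold_c[f] = np.mean((Xc[test] @ w - cut > 0).astype(int) == y[corr_idx][test])
            fold_m[f] = np.mean((Xm @ w - cut > 0).astype(int) == y[miss_idx])
        acc_c[ti] = fold_c.mean()
        acc_m[ti] = fold_m.mean()
    return {"time_ms": times, "correct": acc_c, "miss": acc_m, "n_folds": n_folds}


@dataclass
class SingleTrialDistributions:
    """Per-trial mean decoding accuracies by behavioural outcome."""

    correct: np.ndarray
    miss: np.ndarray
    cohens_d: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.cohens_d)


def single_trial_accuracy_distributions(
    correct_trial_acc: np.ndarray, miss_trial_acc: np.ndarray
) -> SingleTrialDistributions:
    """Cohen's d (pooled SD) between correct and miss per-trial accuracies.

    Flagged as undefined (NaN) when either outcome has fewer than two
    trials or the pooled SD is zero.
    """
    c = np.asarray(correct_trial_acc, dtype=float)
    m = np.asarray(miss_trial_acc, dtype=float)
    if c.size < 2 or m.size < 2:
        warnings.warn("fewer than 2 trials in an outcome: Cohen's d undefined")
        return SingleTrialDistributions(c, m, float("nan"))
    s_pool = np.sqrt(
        ((c.size - 1) * c.var(ddof=1) + (m.size - 1) * m.var(ddof=1))
        / (c.size + m.size - 2)
    )
    if s_pool == 0:
        d = 0.0 if np.isclose(c.mean(), m.mean()) else float("nan")
    else:
        d = float((c.mean() - m.mean()) / s_pool)
    return SingleTrialDistributions(c, m, d)


def split_correct_trials(
    trial_indices: np.ndarray,
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    strata: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Disjoint, exhaustive train/validation/test split of correct trials.

    Default ~80/10/10.  ``strata`` (optional per-trial labels) makes the
    split proportional within each stratum to within one trial.  Requires
    at least 20 trials so validation and test are non-empty.
    """
    idx = np.asarray(trial_indices)
    if idx.size < 20:
        raise ValueError(f"need >= 20 correct trials to split, got {idx.size}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups = (
        [idx]
        if strata is None
        else [idx[np.asarray(strata) == s] for s in np.unique(strata)]
    )
    train, val, test = [], [], []
    for g in groups:
        g = rng.permutation(g)
        n = g.size
        n_val = max(1, int(round(fractions[1] * n)))
        n_test = max(1, int(round(fractions[2] * n)))
        val.append(g[:n_val])
        test.append(g[n_val:n_val + n_test])
        train.append(g[n_val + n_test:])
    return {
        "train": np.sort(np.concatenate(train)),
        "validation": np.sort(np.concatenate(val)),
        "test": np.sort(np.concatenate(test)),
    }


def build_accumulation_traces(
    pair_flags_far: np.ndarray, n_distances: int = N_DISTANCES
) -> np.ndarray:
    """Accumulated-accuracy traces from per-pair farther-member flags.

    ``pair_flags_far`` has shape ``(n_pairs, n_trials)`` ordered as
    :func:`_pair_order`.  Returns ``(n_trials, n_distances)`` where column
    ``d - 1`` is the cumulative mean at distance ``d`` over the
    ``accumulation_count(d)`` classifiers active by then.
    """
    order = _pair_order(n_distances)
    if pair_flags_far.shape[0] != len(order):
        raise ValueError("flag rows must match the pair ordering")
    far = np.array([f for f, _ in order])
    traces = np.empty((pair_flags_far.shape[1], n_distances))
    for d in range(1, n_distances + 1):
        mask = far >= d
        assert mask.sum() == accumulation_count(d, n_distances)
        traces[:, d - 1] = pair_flags_far[mask].mean(axis=0)
    return traces


@dataclass
class PredictionData:
    """Per-subject inputs to the threshold sweep / LOSO transfer."""

    val_traces: np.ndarray  # (n_validation, 15)
    test_traces: np.ndarray  # (n_test_correct + n_miss, 15)
    test_outcomes: np.ndarray  # "correct" | "miss" per test trial
    train_ids: np.ndarray
    validation_ids: np.ndarray
    test_ids: np.ndarray


def prepare_prediction_data(
    binned: DistanceBinnedSet,
    seed: int = 0,
    shrinkage: float | str = DEFAULT_SHRINKAGE,
    correct_outcomes: tuple[str, ...] = CORRECT_OUTCOMES,
) -> PredictionData:
    """Train the 105 first-level classifiers and build accumulation traces.

    ~80% of attended correct trials train the classifiers; half of the
    left-out portion forms the validation set (for the decision threshold)
    and the other half, together with all miss trials, the test set.  Miss
    trials and test-correct trials never enter training or validation
    statistics.
    """
    att = _attended(binned)
    corr_idx, miss_idx = _outcome_indices(att.labels, correct_outcomes)
    if miss_idx.size == 0:
        raise ValueError("no miss trials: outcome prediction undefined")
    parts = split_correct_trials(corr_idx, seed=derive_seed(seed, "split"))
    feats = att.feature_matrix()
    n_bins = att.n_bins
    order = _pair_order(n_bins)
    tr = parts["train"]
    eval_idx = {
        "validation": parts["validation"],
        "test": np.concatenate([parts["test"], miss_idx]),
    }
    flags = {k: np.empty((len(order), v.size)) for k, v in eval_idx.items()}
    for p, (far, near) in enumerate(order):
        Xf = feats[:, far - 1].astype(float)
        Xn = feats[:, near - 1].astype(float)
        Xtr = np.concatenate([Xf[tr], Xn[tr]])
        ytr = np.concatenate([np.ones(tr.size, int), np.zeros(tr.size, int)])
        m0 = Xtr[ytr == 0].mean(axis=0)
        m1 = Xtr[ytr == 1].mean(axis=0)
        S_reg, _ = _shrunk_pooled_cov(Xtr, ytr, shrinkage)
        w = np.linalg.solve(S_reg, m1 - m0)
        cut = 0.5 * (m0 + m1) @ w
        for k, v in eval_idx.items():
            # flag = correctness on the sample at the pair's farther distance
            flags[k][p] = (Xf[v] @ w - cut > 0).astype(float)
    ids = att.labels["trial_id"].to_numpy()
    outcomes = np.array(
        ["correct"] * parts["test"].size + ["miss"] * miss_idx.size, dtype=object
    )
    return PredictionData(
        val_traces=build_accumulation_traces(flags["validation"], n_bins),
        test_traces=build_accumulation_traces(flags["test"], n_bins),
        test_outcomes=outcomes,
        train_ids=ids[tr],
        validation_ids=ids[parts["validation"]],
        test_ids=ids[eval_idx["test"]],
    )


@dataclass
class ThresholdSweep:
    """Balanced prediction accuracy over the (multiple, distance) grid."""

    m_grid: np.ndarray
    accuracy: np.ndarray  # (n_multiples, n_distances)
    val_mean: np.ndarray  # (n_distances,)
    val_sd: np.ndarray  # (n_distances,)


def _balanced_accuracy(pred_miss: np.ndarray, is_miss: np.ndarray) -> float:
    """Mean of per-class accuracies: chance = 0.5 regardless of class sizes."""
    acc_miss = pred_miss[is_miss].mean() if is_miss.any() else np.nan
    acc_corr = (~pred_miss[~is_miss]).mean() if (~is_miss).any() else np.nan
    return float(np.nanmean([acc_miss, acc_corr]))


def sweep_thresholds(
    data: PredictionData, m_grid: np.ndarray | None = None
) -> ThresholdSweep:
    """Second-level outcome classification for every threshold multiple.

    A test trial is labelled *miss* at distance ``d`` when its accumulated
    accuracy falls strictly below ``val_mean(d) - m * val_sd(d)`` (a trial
    exactly on the boundary counts as correct).  Accuracy is the balanced
    (equal-class-weight) accuracy, so chance is 0.5.
    """
    if m_grid is None:
        m_grid = default_m_grid()
    m_grid = np.asarray(m_grid, dtype=float)
    val_mean = data.val_traces.mean(axis=0)
    val_sd = data.val_traces.std(axis=0, ddof=1)
    if np.any(val_sd == 0):
        warnings.warn("degenerate validation SD = 0; boundary equals the mean")
    is_miss = data.test_outcomes == "miss"
    acc = np.empty((m_grid.size, val_mean.size))
    for mi, m in enumerate(m_grid):
        boundary = val_mean - m * val_sd
        pred_miss = data.test_traces < boundary[None, :]
        for d in range(val_mean.size):
            acc[mi, d] = _balanced_accuracy(pred_miss[:, d], is_miss)
    return ThresholdSweep(m_grid=m_grid, accuracy=acc, val_mean=val_mean, val_sd=val_sd)


@dataclass
class PredictionResult:
    """LOSO outcome prediction for one held-out subject."""

    subject: int
    chosen_m: float
    accuracy_by_distance: np.ndarray  # (15,), balanced accuracy
    predicted_miss: np.ndarray  # (n_test, 15) boolean labels at chosen_m
    test_outcomes: np.ndarray


def _best_multiple(sweep: ThresholdSweep) -> float:
    """Best threshold multiple: argmax of distance-averaged accuracy.

    Exact ties are resolved by averaging the tied multiples.
    """
    mean_acc = sweep.accuracy.mean(axis=1)
    best = np.flatnonzero(np.isclose(mean_acc, mean_acc.max()))
    return float(sweep.m_grid[best].mean())


def loso_predict(
    subject_data: list[PredictionData], m_grid: np.ndarray | None = None
) -> list[PredictionResult]:
    """Leave-one-subject-out threshold transfer.

    For each held-out subject the decision multiple is the mean of the
    best-performing multiples of all *other* subjects (avoiding
    circularity), applied to the held-out subject's own validation
    statistics and test traces.
    """
    if len(subject_data) < 3:
        raise ValueError("leave-one-subject-out transfer needs >= 3 subjects")
    sweeps = [sweep_thresholds(d, m_grid) for d in subject_data]
    best = np.array([_best_multiple(s) for s in sweeps])
    results = []
    for s, data in enumerate(subject_data):
        m_star = float(np.mean(np.delete(best, s)))
        boundary = sweeps[s].val_mean - m_star * sweeps[s].val_sd
        pred_miss = data.test_traces < boundary[None, :]
        is_miss = data.test_outcomes == "miss"
        acc = np.array(
            [_balanced_accuracy(pred_miss[:, d], is_miss)
             for d in range(boundary.size)]
        )
        results.append(
            PredictionResult(
                subject=s,
                chosen_m=m_star,
                accuracy_by_distance=acc,
                predicted_miss=pred_miss,
                test_outcomes=data.test_outcomes.copy(),
            )
        )
    return results
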