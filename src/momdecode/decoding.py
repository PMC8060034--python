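"""Linear discriminant decoding with trial-grouped cross-validation.

Two decoders are provided, matching the two kinds of stimulus information in
the MOM task:

* :func:`decode_direction_timecourse` — time-resolved two-class decoding of
  the direction of approach (left vs right), one all-sensor feature vector
  per 5-ms step, 10-fold cross-validation with folds assigned to whole
  trials;
* :func:`decode_distance_pairwise` — all 105 pairwise classifications of
  the 15 ordinal distance bins on direction-pooled features, assembled into
  a 15 x 15 representational dissimilarity matrix (RDM) of cross-validated
  accuracies, with per-trial 0/1 correctness flags retained for the
  downstream error-prediction analyses.

The classifier is a closed-form two-class LDA with shrinkage of the pooled
covariance toward the scaled identity.  Fold assignment always keeps all
samples of a trial together, so train and test sets never share a trial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .epochs import DistanceBinnedSet, EpochSet

__all__ = [
    "LDAModel",
    "CVScheme",
    "TimeResolvedResult",
    "RDM",
    "fit_lda",
    "decode_direction_timecourse",
    "decode_distance_pairwise",
    "per_distance_accuracy",
    "N_DISTANCES",
    "N_PAIRS",
]

N_DISTANCES = 15
N_PAIRS = N_DISTANCES * (N_DISTANCES - 1) // 2  # 105 pairwise classifiers

#: Default shrinkage of the pooled covariance toward (tr(S)/p) * I.
DEFAULT_SHRINKAGE = 0.2


@dataclass
class LDAModel:
    """Fitted two-class linear discriminant.

    The decision rule is ``sign(x @ w - c)`` with ``w = S_reg^-1 (m1 - m0)``
    and the cut at the midpoint of the projected class means; a score of
    exactly zero is assigned deterministically to the first class.
    """

    classes: tuple
    class_means: np.ndarray  # (2, p)
    weights: np.ndarray  # (p,)
    cut: float
    shrinkage: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights - self.cut

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        idx = (scores > 0).astype(int)  # ties (score == 0) -> class 0
        return np.asarray(self.classes, dtype=object)[idx]


def _shrunk_pooled_cov(
    X: np.ndarray, y01: np.ndarray, shrinkage: float | str
) -> tuple[np.ndarray, float]:
    """Pooled within-class covariance with shrinkage toward (tr/p) I."""
    p = X.shape[1]
    Xc = X.copy()
    for c in (0, 1):
        m = X[y01 == c].mean(axis=0)
        Xc[y01 == c] -= m
    n = X.shape[0]
    denom = max(n - 2, 1)
    S = (Xc.T @ Xc) / denom
    if shrinkage == "ledoit-wolf":
        from sklearn.covariance import ledoit_wolf_shrinkage

        lam = float(ledoit_wolf_shrinkage(Xc, assume_centered=True))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'ledoit-wolf'")
    mu = np.trace(S) / p
    S_reg = (1.0 - lam) * S
    # noise-free degenerate input: keep the system solvable with a tiny ridge
    S_reg[np.diag_indices(p)] += lam * mu if mu > 0 else 1e-12
    return S_reg, lam


def fit_lda(
    features: np.ndarray,
    binary_labels: np.ndarray,
    shrinkage: float | str = DEFAULT_SHRINKAGE,
) -> LDAModel:
    """Fit a shrinkage-regularized two-class LDA in closed form.

    ``shrinkage`` is either a fixed lambda in [0, 1] or ``'ledoit-wolf'``
    for the analytic Ledoit-Wolf estimate.  Deterministic given its inputs;
    raises on single-class input.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(binary_labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    y01 = (y == classes[1]).astype(int)
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
        raise ValueError("need at least 2 trials per class")
    m0 = X[y01 == 0].mean(axis=0)
    m1 = X[y01 == 1].mean(axis=0)
    S_reg, lam = _shrunk_pooled_cov(X, y01, shrinkage)
    w = np.linalg.solve(S_reg, m1 - m0)
    cut = float(0.5 * (m0 + m1) @ w)
    return LDAModel(
        classes=tuple(classes.tolist()),
        class_means=np.stack([m0, m1]),
        weights=w,
        cut=cut,
        shrinkage=lam,
    )


@dataclass(frozen=True)
class CVScheme:
    """Trial-grouped k-fold assignment: all samples of a trial share a fold."""

    n_folds: int = 10
    seed: int = 0

    def assign(self, n_trials: int) -> np.ndarray:
        """Fold index (0..n_folds-1) per trial; folds partition the trials."""
        if n_trials < self.n_folds:
            raise ValueError(
                f"{n_trials} trials cannot be split into {self.n_folds} folds"
            )
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n_trials)
        folds = np.empty(n_trials, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, self.n_folds)):
            folds[chunk] = f
        return folds


@dataclass
class TimeResolvedResult:
    """Cross-validated accuracy per time step."""

    time_ms: np.ndarray
    accuracy: np.ndarray  # in [0, 1], equal-fold-weight mean
    n_trials_per_class: dict

    def __post_init__(self) -> None:
        if self.time_ms.size != self.accuracy.size:
            raise ValueError("accuracy length must equal the number of time steps")


@dataclass
class RDM:
    """15 x 15 matrix of pairwise distance-decoding accuracies.

    ``matrix[i, j]`` is the cross-validated accuracy of the classifier for
    distances ``i+1`` vs ``j+1`` (symmetric, diagonal NaN; the lower
    triangle holds the 105 informative entries).  ``pair_flags`` maps each
    pair ``(d_far, d_near)`` with ``d_far > d_near`` to an
    ``(n_trials, 2)`` 0/1 array: column 0 is the test correctness of the
    trial's sample at the farther distance, column 1 at the nearer one.
    """

    matrix: np.ndarray
    pair_flags: dict[tuple[int, int], np.ndarray]
    trial_ids: np.ndarray

    @property
    def n_distances(self) -> int:
        return self.matrix.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """The 105 below-diagonal accuracies in a fixed row-major order."""
        i, j = np.tril_indices(self.n_distances, k=-1)
        return self.matrix[i, j]

    def per_trial_accuracy(self) -> np.ndarray:
        """Mean 0/1 correctness per trial over all pairs and both samples."""
        stack = np.stack([flags for flags in self.pair_flags.values()])
        return np.nanmean(stack, axis=(0, 2))


def _fold_train_test(folds: np.ndarray, f: int) -> tuple[np.ndarray, np.ndarray]:
    test = np.flatnonzero(folds == f)
    train = np.flatnonzero(folds != f)
    if np.intersect1d(test, train).size:  # fold hygiene, by construction
        raise AssertionError("train/test folds overlap")
    return train, test


def _equalize_classes(
    idx: np.ndarray, y01: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Subsample the larger class within ``idx`` to the smaller one's count."""
    a = idx[y01[idx] == 0]
    b = idx[y01[idx] == 1]
    n = min(a.size, b.size)
    if a.size > n:
        a = np.sort(rng.choice(a, size=n, replace=False))
    if b.size > n:
        b = np.sort(rng.choice(b, size=n, replace=False))
    return np.concatenate([a, b])


def decode_direction_timecourse(
    epochs: EpochSet,
    cv: CVScheme = CVScheme(),
    shrinkage: float | str = DEFAULT_SHRINKAGE,
    labels: np.ndarray | None = None,
    equalize_within_fold: bool = True,
) -> TimeResolvedResult:
    """Time-resolved left-vs-right decoding, one all-sensor vector per step.

    Features at each time step are the single-sample vectors across all
    sensors.  Folds group whole trials; within each fold's training set the
    two classes are equalized by seeded subsampling.  ``labels`` overrides
    the label vector (e.g. for permutation nulls) but defaults to the
    ``direction`` column.
    """
    y = np.asarray(labels if labels is not None else epochs.labels["direction"])
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("direction decoding requires exactly two classes")
    y01 = (y == classes[1]).astype(int)
    folds = cv.assign(epochs.n_trials)
    rng = np.random.default_rng(cv.seed + 1)
    split = []
    for f in range(cv.n_folds):
        train, test = _fold_train_test(folds, f)
        if equalize_within_fold:
            train = _equalize_classes(train, y01, rng)
        split.append((train, test))
    n_t = epochs.time_ms.size
    acc = np.empty(n_t)
    data = epochs.data
    for t in range(n_t):
        Xt = data[:, :, t].astype(float)
        fold_acc = np.empty(cv.n_folds)
        for f, (train, test) in enumerate(split):
            pred = _lda_fit_predict(Xt[train], y01[train], Xt[test], shrinkage)
            fold_acc[f] = np.mean(pred == y01[test])
        acc[t] = fold_acc.mean()
    return TimeResolvedResult(
        time_ms=epochs.time_ms.copy(),
        accuracy=acc,
        n_trials_per_class={
            str(classes[0]): int((y01 == 0).sum()),
            str(classes[1]): int((y01 == 1).sum()),
        },
    )


def _lda_fit_predict(
    Xtr: np.ndarray, ytr01: np.ndarray, Xte: np.ndarray, shrinkage: float | str
) -> np.ndarray:
    """Inner LDA fit + 0/1 prediction (hot path; mirrors :func:`fit_lda`)."""
    m0 = Xtr[ytr01 == 0].mean(axis=0)
    m1 = Xtr[ytr01 == 1].mean(axis=0)
    S_reg, _ = _shrunk_pooled_cov(Xtr, ytr01, shrinkage)
    w = np.linalg.solve(S_reg, m1 - m0)
    cut = 0.5 * (m0 + m1) @ w
    return (Xte @ w - cut > 0).astype(int)


def decode_distance_pairwise(
    binned: DistanceBinnedSet,
    cv: CVScheme = CVScheme(),
    shrinkage: float | str = DEFAULT_SHRINKAGE,
    sensors: np.ndarray | None = None,
) -> RDM:
    """All-pairs distance classification on direction-pooled features.

    For each of the 105 unordered distance pairs ``(i, j)`` a classifier is
    trained on the training trials' bin-``i`` and bin-``j`` feature vectors
    and tested on the held-out trials' vectors; every trial contributes one
    sample per class, so classes are balanced by construction.  Per-trial
    0/1 correctness at each of the pair's two distances is retained.
    """
    if not binned.pooled:
        raise ValueError("distance decoding requires direction-pooled input "
                         "(call pool_directions first)")
    feats = binned.feature_matrix(sensors=sensors)  # (trials, bins, F)
    n_tr, n_bins = feats.shape[:2]
    folds = cv.assign(n_tr)
    split = [_fold_train_test(folds, f) for f in range(cv.n_folds)]
    matrix = np.full((n_bins, n_bins), np.nan)
    pair_flags: dict[tuple[int, int], np.ndarray] = {}
    for j, i in itertools.combinations(range(n_bins), 2):  # j < i distances j+1 < i+1
        d_near, d_far = j + 1, i + 1
        Xn = feats[:, j].astype(float)
        Xf = feats[:, i].astype(float)
        flags = np.empty((n_tr, 2))
        for train, test in split:
            Xtr = np.concatenate([Xf[train], Xn[train]])
            ytr = np.concatenate(
                [np.ones(train.size, dtype=int), np.zeros(train.size, dtype=int)]
            )
            m0 = Xtr[ytr == 0].mean(axis=0)
            m1 = Xtr[ytr == 1].mean(axis=0)
            S_reg, _ = _shrunk_pooled_cov(Xtr, ytr, shrinkage)
            w = np.linalg.solve(S_reg, m1 - m0)
            cut = 0.5 * (m0 + m1) @ w
            flags[test, 0] = (Xf[test] @ w - cut > 0).astype(float)  # far = class 1
            flags[test, 1] = (Xn[test] @ w - cut <= 0).astype(float)
        acc = flags.mean()
        matrix[i, j] = matrix[j, i] = acc
        pair_flags[(d_far, d_near)] = flags
    return RDM(matrix=matrix, pair_flags=pair_flags,
               trial_ids=binned.labels["trial_id"].to_numpy())


def per_distance_accuracy(rdm: RDM) -> np.ndarray:
    """Mean of each distance's 14 pairings (element ``d-1`` = distance ``d``)."""
    m = rdm.matrix
    with np.errstate(invalid="ignore"):
        return np.nanmean(m, axis=1)
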