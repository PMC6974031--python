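"""Cross-phase and cross-cue-set linear SVM decoding.

Training always uses conditioning-phase patterns (reward vs. nonreward
cue), testing uses probe-phase patterns of either the same cues (B vs D)
or their associated cues (A vs C). Feature selection ranks voxels by the
absolute t-value of the training contrast; the number of voxels is
chosen by a leave-one-subject-out nested procedure. Chance level is
estimated empirically by permuting test labels with predictions fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from precon_mvpa.behav_stats import StatResult, group_t
from precon_mvpa.ioconfig.volumes import RoiMask

__all__ = [
    "SubjectPatterns",
    "DecodeSpec",
    "DecodingOutcome",
    "rank_voxels",
    "select_voxel_count",
    "svm_decode",
    "svm_predict",
    "empirical_chance",
    "decode_cohort",
    "cross_set_decode",
    "sphere_indices",
    "searchlight_map",
    "DecodeError",
]

#: Label convention: +1 for the reward class (cues B / A), -1 for the
#: nonreward class (cues D / C).
REWARD_LABEL = 1
NONREWARD_LABEL = -1


class DecodeError(ValueError):
    pass


@dataclass
class SubjectPatterns:
    """One subject's train (conditioning) and test (probe) patterns."""

    train_X: np.ndarray          # (n_train_exemplars, n_voxels)
    train_y: np.ndarray          # +1 / -1
    test_X: np.ndarray
    test_y: np.ndarray

    def __post_init__(self) -> None:
        self.train_y = np.asarray(self.train_y, dtype=int)
        self.test_y = np.asarray(self.test_y, dtype=int)
        if self.train_X.shape[1] != self.test_X.shape[1]:
            raise DecodeError("train and test voxel counts differ")


@dataclass
class DecodeSpec:
    """Parameters of one decoding analysis."""

    feature_step: int = 40
    svm_cost: float = 1.0
    n_permutations: int = 10_000
    seed: int = 0
    tail: str = "greater"

    def __post_init__(self) -> None:
        if self.feature_step < 1:
            raise DecodeError("feature step must be >= 1")
        if self.n_permutations < 1:
            raise DecodeError("n_permutations must be >= 1")


@dataclass
class DecodingOutcome:
    """Per-subject decoding results plus the group test vs. chance."""

    table: pd.DataFrame          # subject, accuracy, chance, n_voxels
    group: StatResult
    scheme: str = ""
    roi: str = ""


def rank_voxels(train_X: np.ndarray, train_y: np.ndarray) -> np.ndarray:
    """Voxel indices ordered by descending |t| of the class contrast.

    Pooled-variance two-sample t per voxel (reward minus nonreward
    exemplars); zero-variance voxels get t = 0; exact ties resolve to
    the lower voxel index.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    a = X[y == REWARD_LABEL]
    b = X[y == NONREWARD_LABEL]
    if len(a) < 2 or len(b) < 2:
        raise DecodeError("need >= 2 exemplars per class to rank voxels")
    na, nb = len(a), len(b)
    var = (a.var(axis=0, ddof=1) * (na - 1) + b.var(axis=0, ddof=1) * (nb - 1))
    var /= (na + nb - 2)
    se = np.sqrt(var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / se, 0.0)
    # stable sort on -|t| leaves equal-|t| voxels in ascending index order
    return np.argsort(-np.abs(t), kind="stable")


def _fit_svm(train_X: np.ndarray, train_y: np.ndarray, cost: float) -> SVC:
    if len(np.unique(train_y)) < 2:
        raise DecodeError("training data contain a single class")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(train_X, train_y)
    return clf


def svm_predict(
    train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
    cost: float = 1.0,
) -> np.ndarray:
    """Linear soft-margin SVM predictions; no feature rescaling.

    Decision values of exactly zero predict the reward class
    (deterministic tie rule).
    """
    clf = _fit_svm(train_X, train_y, cost)
    decision = clf.decision_function(test_X)
    if clf.classes_[1] != REWARD_LABEL:       # classes_ is sorted [-1, +1]
        decision = -decision
    return np.where(decision >= 0, REWARD_LABEL, NONREWARD_LABEL)


def svm_decode(
    train_X: np.ndarray, train_y: np.ndarray,
    test_X: np.ndarray, test_y: np.ndarray,
    voxels: np.ndarray | None = None,
    cost: float = 1.0,
) -> float:
    """Accuracy (%) of an SVM trained on one phase, tested on another."""
    if voxels is not None:
        voxels = np.asarray(voxels, dtype=int)
        if voxels.size == 0:
            raise DecodeError("empty voxel subset")
        train_X = train_X[:, voxels]
        test_X = test_X[:, voxels]
    pred = svm_predict(train_X, train_y, test_X, cost=cost)
    return float(np.mean(pred == np.asarray(test_y)) * 100.0)


def empirical_chance(
    predictions: np.ndarray,
    test_labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Mean accuracy (%) of fixed predictions against permuted labels."""
    if n_perm < 1:
        raise DecodeError("n_perm must be >= 1")
    pred = np.asarray(predictions)
    labels = np.asarray(test_labels)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for i in range(n_perm):
        accs[i] = np.mean(pred == rng.permutation(labels))
    return float(accs.mean() * 100.0)


def _count_grid(n_voxels: int, step: int) -> np.ndarray:
    if step > n_voxels:
        return np.array([n_voxels])     # degenerate ROI: use all voxels
    grid = np.arange(step, n_voxels + 1, step)
    if grid[-1] != n_voxels:
        grid = np.append(grid, n_voxels)
    return grid


def select_voxel_count(
    subject_data: Mapping[object, SubjectPatterns],
    spec: DecodeSpec,
    left_out: object,
) -> int:
    """Optimal voxel count chosen without touching the left-out subject.

    For every candidate count, each retained subject contributes the
    accuracy of an SVM trained on their own conditioning patterns
    (top-ranked voxels from their own training contrast) and tested on
    their own probe patterns. The count with the highest mean accuracy
    wins; ties go to the smallest count.
    """
    retained = [s for s in subject_data if s != left_out]
    if len(retained) < 2:
        raise DecodeError("need >= 3 subjects for nested selection")
    n_vox = next(iter(subject_data.values())).train_X.shape[1]
    grid = _count_grid(n_vox, spec.feature_step)
    accs = np.zeros((len(retained), len(grid)))
    for i, subj in enumerate(retained):
        d = subject_data[subj]
        order = rank_voxels(d.train_X, d.train_y)
        for j, count in enumerate(grid):
            accs[i, j] = svm_decode(
                d.train_X, d.train_y, d.test_X, d.test_y,
                voxels=order[:count], cost=spec.svm_cost)
    mean_acc = accs.mean(axis=0)
    return int(grid[int(np.argmax(mean_acc))])   # argmax -> first (smallest) max


def decode_cohort(
    subject_data: Mapping[object, SubjectPatterns],
    spec: DecodeSpec,
    scheme: str = "",
    roi: str = "",
) -> DecodingOutcome:
    """Full nested LOSO decoding over a cohort, with empirical chance.

    Per subject: the voxel count comes from :func:`select_voxel_count`
    with that subject left out; ranking, training and testing then use
    only that subject's own data; chance is the permutation average of
    the subject's fixed predictions against shuffled test labels.
    Group-level inference is a one-sample t of accuracy minus chance.
    """
    rows = []
    for idx, subj in enumerate(subject_data):
        count = select_voxel_count(subject_data, spec, left_out=subj)
        d = subject_data[subj]
        order = rank_voxels(d.train_X, d.train_y)
        voxels = order[:count]
        pred = svm_predict(d.train_X[:, voxels], d.train_y,
                           d.test_X[:, voxels], cost=spec.svm_cost)
        acc = float(np.mean(pred == d.test_y) * 100.0)
        chance = empirical_chance(pred, d.test_y, spec.n_permutations,
                                  seed=spec.seed + idx)
        rows.append({"subject": subj, "accuracy": acc, "chance": chance,
                     "n_voxels": count})
    table = pd.DataFrame(rows)
    group = group_t(table["accuracy"] - table["chance"], 0.0,
                    tail=spec.tail, name="accuracy_vs_chance")
    return DecodingOutcome(table=table, group=group, scheme=scheme, roi=roi)


def cross_set_decode(
    train_by_set: Mapping[int, tuple[np.ndarray, np.ndarray]],
    test_by_set: Mapping[int, tuple[np.ndarray, np.ndarray]],
    spec: DecodeSpec,
    voxels: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-cue-set-out decoding (one subject).

    Trains on the pooled conditioning patterns of all sets but one and
    tests on the held-out set's probe patterns; the reported accuracy is
    the mean of the fold accuracies. Also returns pooled predictions and
    labels for the empirical-chance estimate.
    """
    sets = sorted(train_by_set)
    if sorted(test_by_set) != sets:
        raise DecodeError("train and test cue sets differ")
    if len(sets) < 2:
        raise DecodeError("need >= 2 cue sets")
    fold_accs, all_pred, all_labels = [], [], []
    for held_out in sets:
        X_tr = np.vstack([train_by_set[s][0] for s in sets if s != held_out])
        y_tr = np.concatenate([train_by_set[s][1] for s in sets if s != held_out])
        X_te, y_te = test_by_set[held_out]
        if voxels is not None:
            X_tr, X_te = X_tr[:, voxels], X_te[:, voxels]
        pred = svm_predict(X_tr, y_tr, X_te, cost=spec.svm_cost)
        fold_accs.append(np.mean(pred == np.asarray(y_te)) * 100.0)
        all_pred.append(pred)
        all_labels.append(np.asarray(y_te))
    return (float(np.mean(fold_accs)), np.asarray(fold_accs),
            np.concatenate(all_pred), np.concatenate(all_labels))


def sphere_indices(
    center: Sequence[int],
    mask: RoiMask,
    radius_mm: float,
) -> np.ndarray:
    """Positions (into the mask's voxel list) within a searchlight sphere.

    A voxel belongs to the sphere when its center-to-center Euclidean
    distance from the sphere center is strictly less than the radius;
    spheres are truncated at mask edges. At 8 mm radius on a 2 mm
    isotropic lattice the untruncated sphere holds 251 voxels.
    """
    if radius_mm <= 0:
        raise DecodeError("radius must be > 0")
    center = np.asarray(center, dtype=float)
    offsets_mm = (mask.indices - center) * mask.voxel_size_mm
    dist = np.sqrt((offsets_mm ** 2).sum(axis=1))
    return np.flatnonzero(dist < radius_mm)


def searchlight_map(
    patterns: np.ndarray,
    mask: RoiMask,
    statistic: Callable[[np.ndarray], float],
    radius_mm: float = 8.0,
) -> np.ndarray:
    """Evaluate a pattern statistic in a moving sphere over mask voxels.

    ``patterns`` is (exemplars x mask voxels); the statistic receives the
    exemplars restricted to one sphere's voxels and its value is written
    at the sphere center. Voxels outside the mask stay NaN.
    """
    if patterns.shape[1] != mask.n_voxels:
        raise DecodeError("patterns do not match the mask voxel count")
    out = np.full(mask.shape, np.nan)
    for pos in range(mask.n_voxels):
        sphere = sphere_indices(mask.indices[pos], mask, radius_mm)
        if sphere.size == 0:
            raise DecodeError("empty searchlight sphere")
        i, j, k = mask.indices[pos]
        out[i, j, k] = statistic(patterns[:, sphere])
    return out
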