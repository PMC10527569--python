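"""Serial correlation-based fusion of multi-source feature matrices.

Feature vectors from several extractors are concatenated column-wise
("serial fusion"), consecutive column pairs are scored with the Pearson
correlation across samples, and the pairs are split into a positively
correlated set and a weakly correlated set.  Both sets are scored with a
1-nearest-neighbour cross-validated accuracy and the better one is kept.

The correlation is evaluated with the raw-moment form

    r = (n * S_xy - S_x * S_y) / sqrt((n * S_xx - S_x^2) * (n * S_yy - S_y^2))

which is algebraically the standard Pearson coefficient; constant columns
get r = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureMatrix

__all__ = [
    "FusionResult",
    "AlignmentError",
    "FitnessError",
    "serial_fuse",
    "pairwise_correlation",
    "knn_fitness",
    "fuse_select",
]


class AlignmentError(ValueError):
    """Input matrices disagree on sample count or labels."""


class FitnessError(ValueError):
    """Labels unusable for a classification fitness (e.g., a single class)."""


@dataclass
class FusionResult:
    """Outcome of correlation-based fusion."""

    fused: FeatureMatrix
    pair_index: list[tuple[int, int]]
    pair_r: np.ndarray
    positive_set: FeatureMatrix | None
    weak_set: FeatureMatrix | None
    positive_columns: list[int] = field(default_factory=list)
    weak_columns: list[int] = field(default_factory=list)
    fitness_positive: float = 0.0
    fitness_weak: float = 0.0
    chosen: str = "positive"

    @property
    def chosen_set(self) -> FeatureMatrix:
        out = self.positive_set if self.chosen == "positive" else self.weak_set
        assert out is not None
        return out

    @property
    def chosen_columns(self) -> list[int]:
        return self.positive_columns if self.chosen == "positive" else self.weak_columns

    def summary(self) -> dict:
        return {
            "n_pairs": len(self.pair_index),
            "pair_r": [float(r) for r in self.pair_r],
            "n_positive": len(self.positive_columns),
            "n_weak": len(self.weak_columns),
            "fitness_positive": float(self.fitness_positive),
            "fitness_weak": float(self.fitness_weak),
            "chosen": self.chosen,
        }


def serial_fuse(mats: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature matrices column-wise, preserving input order."""
    if not mats:
        raise ValueError("serial_fuse requires at least one matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.n_samples != first.n_samples:
            raise AlignmentError(
                f"sample counts differ: {first.n_samples} vs {m.n_samples}"
            )
        if not np.array_equal(m.labels, first.labels):
            raise AlignmentError("label vectors differ between input matrices")
    values = np.hstack([m.values for m in mats])
    names = [n for m in mats for n in m.feature_names]
    return FeatureMatrix(values=values, labels=first.labels.copy(), feature_names=names)


def pairwise_correlation(fused: FeatureMatrix):
    """Pearson r for consecutive column pairs of the fused matrix.

    Columns are paired disjointly in order ((0,1), (2,3), ...); with an odd
    number of columns the last column is paired with itself.  Returns
    ``(pair_index, pair_r)``.
    """
    x = fused.values
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to correlate")
    k = x.shape[1]
    pairs: list[tuple[int, int]] = [(i, i + 1) for i in range(0, k - 1, 2)]
    if k % 2 == 1:
        pairs.append((k - 1, k - 1))
    rs = np.empty(len(pairs))
    for p, (i, j) in enumerate(pairs):
        xi, xj = x[:, i], x[:, j]
        sx, sy = xi.sum(), xj.sum()
        num = n * (xi * xj).sum() - sx * sy
        den2 = (n * (xi * xi).sum() - sx * sx) * (n * (xj * xj).sum() - sy * sy)
        rs[p] = 0.0 if den2 <= 0 else num / np.sqrt(den2)
    return pairs, np.clip(rs, -1.0, 1.0)


def _fold_splitter(labels: np.ndarray, folds: int, seed):
    """Stratified folds, degrading to fewer folds (or plain folds) on tiny classes."""
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise FitnessError("fitness needs at least 2 classes")
    min_count = int(counts.min())
    if min_count >= 2:
        n_folds = max(2, min(folds, min_count))
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return KFold(n_splits=2, shuffle=True, random_state=seed)


def _knn_predict(train_x, train_y, test_x, k: int):
    if k == 1:  # fast exact path: nearest row by Euclidean distance
        nearest = np.argmin(cdist(test_x, train_x), axis=1)
        return train_y[nearest]
    clf = KNeighborsClassifier(n_neighbors=min(k, len(train_y)))
    clf.fit(train_x, train_y)
    return clf.predict(test_x)


def knn_fitness(mat: FeatureMatrix, k: int = 1, folds: int = 10, seed: int = 0) -> float:
    """Mean stratified cross-validated accuracy of a Euclidean k-NN.

    k=1 is the "fine" k-NN configuration used throughout the fusion and
    selection stages.  Fold assignment is seeded, so the value is
    deterministic for a given (data, k, folds, seed).
    """
    splitter = _fold_splitter(mat.labels, folds, seed)
    x, y = mat.values, mat.labels
    accs = []
    for train_idx, test_idx in splitter.split(x, y):
        pred = _knn_predict(x[train_idx], y[train_idx], x[test_idx], k)
        accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))


def fuse_select(
    mats: list[FeatureMatrix],
    threshold: float = 0.5,
    k: int = 1,
    folds: int = 10,
    seed: int = 0,
) -> FusionResult:
    """Fuse, correlate, partition by correlation sign, keep the fitter set.

    Pairs with r > ``threshold`` contribute both columns to the positive
    set; all other pairs go to the weak set.  Each non-empty set is scored
    with :func:`knn_fitness`; an empty set scores 0.  Ties go to the
    positive set.
    """
    fused = serial_fuse(mats)
    pairs, rs = pairwise_correlation(fused)
    pos_cols: list[int] = []
    weak_cols: list[int] = []
    for (i, j), r in zip(pairs, rs):
        cols = [i] if i == j else [i, j]
        (pos_cols if r > threshold else weak_cols).extend(cols)

    def build(cols: list[int]):
        return fused.select_columns(cols) if cols else None

    pos_set, weak_set = build(pos_cols), build(weak_cols)
    fit_pos = knn_fitness(pos_set, k, folds, seed) if pos_set is not None else 0.0
    fit_weak = knn_fitness(weak_set, k, folds, seed) if weak_set is not None else 0.0
    chosen = "positive" if fit_pos >= fit_weak else "weak"
    if pos_set is None:
        chosen = "weak"
    elif weak_set is None:
        chosen = "positive"
    return FusionResult(
        fused=fused,
        pair_index=pairs,
        pair_r=rs,
        positive_set=pos_set,
        weak_set=weak_set,
        positive_columns=pos_cols,
        weak_columns=weak_cols,
        fitness_positive=fit_pos,
        fitness_weak=fit_weak,
        chosen=chosen,
    )
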