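"""Kennard-Stone maximin sample-set partitioning.

The Kennard-Stone algorithm deterministically picks a training subset that
spans the data: start from the two most distant samples, then repeatedly
add the candidate whose minimal Euclidean distance to the already selected
set is largest. The remaining samples form the prediction set and, by
construction, fall inside the training set's coverage.

For a two-class authentication problem the selection runs separately
inside each class and the two selections are merged, so both classes stay
represented in both subsets at the requested proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

from .dataset import NEG, POS, SpectralDataset


@dataclass
class SplitResult:
    """Training/prediction index sets into the dataset plus per-class counts."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    per_class_counts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        overlap = set(self.train_indices) & set(self.test_indices)
        if overlap:
            raise ValueError(f"train/test overlap at indices {sorted(overlap)[:5]}")


def kennard_stone(X: np.ndarray, n_train: int) -> np.ndarray:
    """Maximin selection of ``n_train`` row indices, in selection order.

    Deterministic: distance ties are broken by the lowest index, both for
    the initial farthest pair and at every subsequent step.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples")
    if not 2 <= n_train <= m:
        raise ValueError(f"n_train must be in [2, {m}], got {n_train}")

    dist = squareform(pdist(X))
    # initial pair: maximal distance, lexicographically smallest on ties
    flat = np.argmax(dist)  # row-major scan -> lowest (i, j) first
    i, j = divmod(flat, m)
    selected = [min(i, j), max(i, j)]
    remaining = np.ones(m, dtype=bool)
    remaining[selected] = False

    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    while len(selected) < n_train:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))  # first max = lowest index
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, dist[nxt])
    return np.array(selected, dtype=int)


def _resolve_counts(
    dataset: SpectralDataset,
    train_fraction: float | None,
    train_counts: dict[str, int] | None,
) -> dict[str, int]:
    if (train_fraction is None) == (train_counts is None):
        raise ValueError("give exactly one of train_fraction or train_counts")
    counts: dict[str, int] = {}
    for label in (POS, NEG):
        m = int((dataset.labels == label).sum())
        want = train_counts[label] if train_counts else int(round(train_fraction * m))
        if not 2 <= want <= m - 1:
            raise ValueError(
                f"class {label}: training count {want} outside [2, {m - 1}] "
                f"(class size {m})"
            )
        counts[label] = want
    return counts


def split_per_class(
    dataset: SpectralDataset,
    train_fraction: float | None = None,
    train_counts: dict[str, int] | None = None,
) -> SplitResult:
    """Run Kennard-Stone inside each class and merge the selections.

    ``train_fraction`` applies one proportion to both classes (count
    rounded to nearest); ``train_counts`` fixes per-class counts exactly.
    """
    counts = _resolve_counts(dataset, train_fraction, train_counts)
    train, test, per_class = [], [], {}
    for label in (POS, NEG):
        idx = dataset.class_indices(label)
        chosen = kennard_stone(dataset.absorbance[idx], counts[label])
        chosen_global = idx[chosen]
        rest = np.setdiff1d(idx, chosen_global)
        train.append(chosen_global)
        test.append(rest)
        per_class[label] = (len(chosen_global), len(rest))
    return SplitResult(
        train_indices=np.concatenate(train),
        test_indices=np.concatenate(test),
        per_class_counts=per_class,
    )


class KennardStoneSplitter(BaseEstimator):
    """sklearn-style wrapper yielding one deterministic per-class split.

    ``split(X, y)`` follows the cross-validator protocol (yields a single
    (train, test) pair) so it can feed ``cross_validate`` and friends.
    """

    def __init__(self, train_fraction: float | None = None,
                 train_counts: dict[str, int] | None = None):
        self.train_fraction = train_fraction
        self.train_counts = train_counts

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1

    def split(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        ds = SpectralDataset(
            wavenumbers=np.arange(X.shape[1], dtype=float), absorbance=X, labels=y
        )
        res = split_per_class(ds, self.train_fraction, self.train_counts)
        yield res.train_indices, res.test_indices
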