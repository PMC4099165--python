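"""Stahel-Donoho projection-pursuit outlyingness diagnosis.

A sample's Stahel-Donoho outlyingness is its worst-case robustly
standardised distance from the data's centre over one-dimensional
projections:

    out(x_i) = max_a |a.x_i - med_j(a.x_j)| / (1.4826 * MAD_j(a.x_j))

where the maximum runs over unit directions ``a``, ``med`` is the sample
median and MAD the median absolute deviation (the 1.4826 factor makes the
scale Gaussian-consistent, so a cutoff of 3 reads as "beyond ~3 robust
standard deviations"). The exact supremum over all directions is
intractable in thousands of dimensions; the standard stochastic
approximation maximises over random unit vectors plus normalised
pairwise-difference directions, which point at the outliers themselves.

Diagnosis runs within each class separately by default: a genuine member
of the minority class must not look aberrant merely because the majority
class dominates the pooled median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import NEG, POS, SpectralDataset

_MAD_CONSISTENCY = 1.4826  # makes MAD consistent with the Gaussian sd
_DEGENERATE_SCALE = 1e-12


@dataclass
class OutlyingnessResult:
    """Per-sample scores, the boolean outlier mask and the settings used."""

    values: np.ndarray
    mask: np.ndarray
    cutoff: float
    n_directions: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if (self.values < 0).any():
            raise ValueError("outlyingness values must be nonnegative")
        if not np.array_equal(self.mask, self.values > self.cutoff):
            raise ValueError("mask must equal values > cutoff exactly")


def generate_directions(X: np.ndarray, n_random: int = 500, seed: int = 0) -> np.ndarray:
    """Candidate projection directions: random unit vectors + pair differences.

    Returns up to ``n_random`` standard-normal directions plus up to
    ``n_random`` normalised pairwise differences x_i - x_j (all pairs when
    few, a seeded subsample otherwise). Every returned row has unit
    Euclidean norm; zero-norm candidates are dropped.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)

    random_dirs = rng.standard_normal((n_random, p))

    n_pairs = n * (n - 1) // 2
    if n_pairs <= n_random:
        pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    else:
        # sample index pairs without materialising all of them
        flat = rng.choice(n_pairs, size=n_random, replace=False)
        i = (np.ceil(np.sqrt(2 * (flat + 1) + 0.25) - 0.5)).astype(int)
        j = (flat - (i * (i - 1)) // 2).astype(int)
        pairs = np.column_stack([j, i])  # j < i by construction
    diffs = X[pairs[:, 0]] - X[pairs[:, 1]]

    cands = np.vstack([random_dirs, diffs])
    norms = np.linalg.norm(cands, axis=1)
    keep = norms > _DEGENERATE_SCALE
    if not keep.any():
        raise ValueError("all candidate directions are degenerate")
    return cands[keep] / norms[keep, None]


def sde_outlyingness(X: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Max robust z-score of each sample over the given unit directions.

    Directions whose scaled MAD falls below 1e-12 carry no robust scale
    information and are skipped; if every direction degenerates this way
    the data admit no diagnosis and an error is raised.
    """
    X = np.asarray(X, dtype=float)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if directions.shape[0] < 1:
        raise ValueError("need at least one direction")

    proj = X @ directions.T  # (n, d)
    med = np.median(proj, axis=0)
    absdev = np.abs(proj - med)
    scale = _MAD_CONSISTENCY * np.median(absdev, axis=0)
    ok = scale > _DEGENERATE_SCALE
    if not ok.any():
        raise ValueError("all projections degenerate (zero robust scale)")
    return (absdev[:, ok] / scale[ok]).max(axis=1)


class SDEOutlierDetector(BaseEstimator):
    """Stahel-Donoho outlier detector with the field's cutoff-3 convention.

    Parameters
    ----------
    cutoff : flag a sample when its outlyingness is strictly above this
        value (default 3.0, ~3 robust sds).
    n_random : number of random directions, and cap on pair-difference
        directions (default 500).
    random_state : seed for direction generation; mandatory determinism.

    Attributes (after :meth:`fit`)
    ------------------------------
    outlyingness_ : per-sample scores.
    outlier_mask_ : boolean, True where flagged.
    n_directions_ : directions actually used.
    """

    def __init__(self, cutoff: float = 3.0, n_random: int = 500, random_state: int = 0):
        self.cutoff = cutoff
        self.n_random = n_random
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        directions = generate_directions(X, self.n_random, self.random_state)
        self.outlyingness_ = sde_outlyingness(X, directions)
        self.outlier_mask_ = self.outlyingness_ > self.cutoff
        self.n_directions_ = directions.shape[0]
        return self

    def fit_predict(self, X, y=None):
        """sklearn outlier convention: -1 for outliers, +1 for inliers."""
        self.fit(X)
        return np.where(self.outlier_mask_, -1, 1)

    def result(self) -> OutlyingnessResult:
        return OutlyingnessResult(
            values=self.outlyingness_, mask=self.outlier_mask_,
            cutoff=self.cutoff, n_directions=self.n_directions_,
            seed=self.random_state,
        )


def flag_and_remove(
    dataset: SpectralDataset,
    cutoff: float = 3.0,
    n_random: int = 500,
    seed: int = 0,
    per_class: bool = True,
) -> tuple[SpectralDataset, dict[str, OutlyingnessResult]]:
    """Diagnose and drop aberrant spectra; returns (clean dataset, results).

    With ``per_class`` (default) the diagnosis runs independently inside
    each label group. Scores exactly at the cutoff are kept (flagging is
    strictly "above"). Raises if any class starts with, or is reduced
    below, 3 samples.
    """
    groups = [POS, NEG] if per_class else [None]
    results: dict[str, OutlyingnessResult] = {}
    keep = np.ones(dataset.n, dtype=bool)
    for group in groups:
        idx = dataset.class_indices(group) if group else np.arange(dataset.n)
        if idx.size < 3:
            raise ValueError(f"class {group!r} has fewer than 3 samples")
        det = SDEOutlierDetector(cutoff=cutoff, n_random=n_random, random_state=seed)
        det.fit(dataset.absorbance[idx])
        results[group or "ALL"] = det.result()
        keep[idx[det.outlier_mask_]] = False
        if (keep[idx]).sum() < 3:
            raise ValueError(f"outlier removal left class {group!r} below 3 samples")
    return dataset.subset(np.flatnonzero(keep)), results
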