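"""Two-class PLS discriminant analysis with MCCV latent-variable selection.

PLSDA regresses a dummy-coded class-membership response on the spectral
matrix. With two classes the ideal response for a sample is the row
(+1, -1) if it belongs to the positive (protected-origin) class and
(-1, +1) otherwise. A new sample is assigned to the positive class
exactly when the first predicted response exceeds zero; the second
column is redundant (it is the negation of the first) and is retained
for diagnostics only.

The PLS fit uses the SIMPLS algorithm (de Jong, 1993): latent variables
are extracted from the cross-product matrix S = X'Y directly, without
deflating X, which makes truncating a fitted model to fewer components
free — the property the Monte-Carlo cross-validation (MCCV) below
exploits. X and Y are mean-centred, not autoscaled: spectra share units
and autoscaling would inflate noise wavelengths.

The number of latent variables A is the key complexity parameter. It is
chosen by MCCV: T random stratified splits of the training set into a
secondary training and secondary prediction half; for each candidate A
the misclassification rate

    MR(A) = (1/T) * sum_i M_i / P_i * 100%

(M_i misclassified, P_i predicted objects in repetition i) is
accumulated, and the smallest A attaining the minimal MR wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import NEG, POS


@dataclass(frozen=True)
class ClassCodeBook:
    """Two-class dummy coding: POS -> (+1, -1), NEG -> (-1, +1)."""

    classes: tuple[str, str] = (POS, NEG)

    def encode(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels, dtype=object)
        unknown = set(labels) - set(self.classes)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
        pos = labels == self.classes[0]
        Y = np.where(pos[:, None], [1.0, -1.0], [-1.0, 1.0])
        return Y

    def decode(self, responses: np.ndarray) -> np.ndarray:
        return assign_classes(responses, self)


def encode_labels(labels, codebook: ClassCodeBook | None = None) -> np.ndarray:
    """Length-n label vector -> n x 2 ideal response matrix of +/-1."""
    return (codebook or ClassCodeBook()).encode(labels)


def assign_classes(responses: np.ndarray, codebook: ClassCodeBook | None = None) -> np.ndarray:
    """Threshold rule: positive class iff the first response is strictly > 0."""
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[1] != 2:
        raise ValueError("responses must be an m x 2 matrix")
    codebook = codebook or ClassCodeBook()
    return np.where(responses[:, 0] > 0, codebook.classes[0], codebook.classes[1]).astype(object)


# ---------------------------------------------------------------------------
# SIMPLS core


class RankDeficiencyError(ValueError):
    """Deflation exhausted the data's rank before the requested count."""

    def __init__(self, achieved: int, requested: int):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"rank deficiency: only {achieved} latent variables extractable, "
            f"{requested} requested"
        )


def _simpls(X0: np.ndarray, Y0: np.ndarray, n_components: int):
    """SIMPLS on centred X0 (n x p) and Y0 (n x q).

    Returns (R, T, P, Q): x-weights, scores, x-loadings, y-loadings, each
    with ``n_components`` columns, such that the coefficient matrix for
    the first a components is R[:, :a] @ Q[:, :a].T.
    """
    n, p = X0.shape
    q = Y0.shape[1]
    A = n_components
    R = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((q, A))
    V = np.zeros((p, A))  # orthonormal basis of x-loadings

    S = X0.T @ Y0
    s_first = None
    t_scale = np.linalg.norm(X0)
    for a in range(A):
        # dominant right singular vector of the (deflated) cross-product
        _, svals, Vt = np.linalg.svd(S, full_matrices=False)
        if s_first is None:
            s_first = svals[0]
        # relative threshold: deflation residue of an exhausted rank sits
        # at round-off relative to the initial cross-product magnitude
        if svals[0] <= max(s_first, 1.0) * 1e-12:
            raise RankDeficiencyError(a, A)
        r = S @ Vt[0]
        t = X0 @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt <= 1e-12 * t_scale * np.linalg.norm(r):
            raise RankDeficiencyError(a, A)
        t /= normt
        r /= normt
        p_load = X0.T @ t
        q_load = Y0.T @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)

        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, p_load, q_load, v
    return R, T, P, Q


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Two-class PLSDA via SIMPLS with mean-centring.

    Parameters
    ----------
    n_components : number of latent variables A, 1 <= A <= min(n-1, p).

    Attributes (after :meth:`fit`)
    ------------------------------
    x_mean_, y_mean_ : centring vectors.
    coef_ : (p, 2) regression matrix; predicted response =
        (x - x_mean_) @ coef_ + y_mean_.
    x_weights_, x_scores_, x_loadings_, y_loadings_ : SIMPLS matrices
        (p x A, n x A, p x A, 2 x A) for diagnostics.
    classes_ : the codebook's (POS, NEG) pair.
    """

    def __init__(self, n_components: int = 2, codebook: ClassCodeBook | None = None):
        self.n_components = n_components
        self.codebook = codebook

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 training samples")
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components must be in [1, {min(n - 1, p)}], got {self.n_components}"
            )
        if np.ptp(X, axis=0).max() == 0:
            raise ValueError("all spectral columns are constant")
        codebook = self.codebook or ClassCodeBook()
        Y = codebook.encode(y)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        X0 = X - self.x_mean_
        Y0 = Y - self.y_mean_
        R, T, P, Q = _simpls(X0, Y0, self.n_components)
        self.x_weights_, self.x_scores_ = R, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.coef_ = R @ Q.T
        self.codebook_ = codebook
        self.classes_ = np.array(codebook.classes, dtype=object)
        return self

    def predict_responses(self, X, n_components: int | None = None) -> np.ndarray:
        """Predicted 2-column response matrix, optionally truncated to
        fewer latent variables than were fitted."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_mean_.shape[0]:
            raise ValueError(
                f"expected {self.x_mean_.shape[0]} wavelength points, got {X.shape[1]}"
            )
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        B = self.x_weights_[:, :a] @ self.y_loadings_[:, :a].T
        return (X - self.x_mean_) @ B + self.y_mean_

    def decision_function(self, X) -> np.ndarray:
        return self.predict_responses(X)[:, 0]

    def predict(self, X) -> np.ndarray:
        return assign_classes(self.predict_responses(X), self.codebook_)


def fit_pls(X, Y, n_lv: int) -> PLSDAClassifier:
    """Fit PLSDA from an already dummy-coded n x 2 response matrix."""
    codebook = ClassCodeBook()
    labels = codebook.decode(np.asarray(Y, dtype=float))
    return PLSDAClassifier(n_components=n_lv).fit(X, labels)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


@dataclass
class MCCVResult:
    """MCCV misclassification rates (%) per latent-variable count."""

    mr_by_lv: np.ndarray
    chosen_lv: int
    T: int
    split_fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.mr_by_lv = np.asarray(self.mr_by_lv, dtype=float)
        if ((self.mr_by_lv < 0) | (self.mr_by_lv > 100)).any():
            raise ValueError("misclassification rates must lie in [0, 100]")
        if self.mr_by_lv[self.chosen_lv - 1] != self.mr_by_lv.min():
            raise ValueError("chosen_lv must attain the minimal MR")


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Random stratified split; each class contributes round(fraction*m) to
    the first half, with both halves guaranteed non-empty per class.

    One global permutation is drawn and partitioned within each class, so
    the split (and hence the MCCV rate) is invariant under renaming the
    two classes."""
    perm = rng.permutation(labels.size)
    first, second = [], []
    for label in (POS, NEG):
        idx = perm[labels[perm] == label]
        if idx.size < 2:
            raise ValueError(f"class {label} needs >= 2 samples for a split")
        k = int(round(fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        first.append(idx[:k])
        second.append(idx[k:])
    return np.concatenate(first), np.concatenate(second)


def mccv_select_lv(
    X: np.ndarray,
    labels: np.ndarray,
    max_lv: int = 20,
    T: int = 20,
    fraction: float = 0.5,
    seed: int = 0,
) -> MCCVResult:
    """Choose the latent-variable count by Monte-Carlo cross-validation.

    Over ``T`` seeded stratified ``fraction``/(1-fraction) splits of the
    training data, each candidate count a in 1..max_lv is scored by the
    averaged percent misclassification rate; the smallest count attaining
    the minimum is selected. One SIMPLS fit per split at ``max_lv``
    components serves every candidate count, since a SIMPLS model
    truncates exactly.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rates = np.zeros((T, max_lv))
    grid = max_lv  # candidate counts every repetition could extract
    for t in range(T):
        tr, pr = _stratified_split(labels, fraction, rng)
        feasible = min(tr.size - 1, X.shape[1])
        if max_lv > feasible:
            raise ValueError(
                f"max_lv={max_lv} exceeds the {feasible} components feasible "
                f"for a secondary training set of {tr.size} samples"
            )
        try:
            model = PLSDAClassifier(n_components=max_lv).fit(X[tr], labels[tr])
        except RankDeficiencyError as exc:
            # near-exactly low-rank data: score only the extractable counts
            if exc.achieved < 1:
                raise
            grid = min(grid, exc.achieved)
            model = PLSDAClassifier(n_components=exc.achieved).fit(X[tr], labels[tr])
        truth = labels[pr]
        for a in range(1, model.n_components + 1):
            pred = assign_classes(model.predict_responses(X[pr], n_components=a))
            rates[t, a - 1] = np.mean(pred != truth) * 100.0
    mr = rates[:, :grid].mean(axis=0)
    chosen = int(np.argmin(mr)) + 1  # first minimum = smallest count
    return MCCVResult(mr_by_lv=mr, chosen_lv=chosen, T=T, split_fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# Confusion metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with POS as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def sensitivity(self) -> float:
        """TP / (TP + FN): fraction of genuine positives recognised."""
        if self.tp + self.fn == 0:
            raise ValueError("sensitivity undefined: no positive objects")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """TN / (TN + FP): fraction of negatives correctly rejected."""
        if self.tn + self.fp == 0:
            raise ValueError("specificity undefined: no negative objects")
        return self.tn / (self.tn + self.fp)


def evaluate(true_labels, predicted) -> tuple[ConfusionCounts, float, float]:
    """Confusion counts plus (sensitivity, specificity), POS positive."""
    true_labels = np.asarray(true_labels, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    counts = ConfusionCounts(
        tp=int(((true_labels == POS) & (predicted == POS)).sum()),
        fn=int(((true_labels == POS) & (predicted == NEG)).sum()),
        tn=int(((true_labels == NEG) & (predicted == NEG)).sum()),
        fp=int(((true_labels == NEG) & (predicted == POS)).sum()),
    )
    return counts, counts.sensitivity, counts.specificity
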