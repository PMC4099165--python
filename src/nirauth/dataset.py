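"""Labelled spectral matrices and their delimited-text I/O.

A :class:`SpectralDataset` is the currency every stage of the authentication
pipeline trades in: a strictly increasing wavenumber axis (cm^-1), an
``n x p`` absorbance matrix whose columns align with that axis, a binary
origin label per sample and a unique sample identifier per row.

The positive class (``POS``) is the protected-origin product; the negative
class (``NEG``) is everything else. Instrument exports frequently list
wavenumbers in descending order, so the CSV reader canonicalises to
ascending order on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical label codes. ``A``/``N`` are accepted as aliases on read.
POS = "POS"
NEG = "NEG"

_LABEL_ALIASES = {"POS": POS, "NEG": NEG, "A": POS, "N": NEG}

#: CSV column holding sample identifiers / labels.
SAMPLE_ID_COLUMN = "sample_id"
LABEL_COLUMN = "label"


@dataclass
class SpectralDataset:
    """Wavenumber axis + absorbance matrix + labels + sample ids.

    Parameters
    ----------
    wavenumbers : (p,) float array, strictly increasing, in cm^-1.
    absorbance : (n, p) float array, columns aligned with ``wavenumbers``.
    labels : (n,) array of ``"POS"`` / ``"NEG"``.
    sample_ids : (n,) array of unique strings.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"s{i:04d}" for i in range(self.absorbance.shape[0])], dtype=object
            )
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if n < 1 or p < 3:
            raise ValueError(f"need n >= 1 samples and p >= 3 points, got n={n}, p={p}")
        if self.wavenumbers.shape != (p,):
            raise ValueError(
                f"wavenumbers length {self.wavenumbers.shape} does not match p={p}"
            )
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.isnan(self.absorbance).any():
            i, j = np.argwhere(np.isnan(self.absorbance))[0]
            raise ValueError(
                f"missing absorbance value at sample {self.sample_ids[i]!r}, "
                f"wavenumber {self.wavenumbers[j]:g}"
            )
        if self.labels.shape != (n,) or self.sample_ids.shape != (n,):
            raise ValueError("labels and sample_ids must have one entry per sample")
        bad = set(self.labels) - {POS, NEG}
        if bad:
            raise ValueError(f"labels must be {POS!r}/{NEG!r}; found {sorted(bad)}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    # -- conveniences -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.absorbance.shape[0]

    @property
    def p(self) -> int:
        return self.absorbance.shape[1]

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        """New dataset restricted to the given sample rows (order kept)."""
        rows = np.asarray(rows)
        return replace(
            self,
            absorbance=self.absorbance[rows],
            labels=self.labels[rows],
            sample_ids=self.sample_ids[rows],
        )

    def with_absorbance(self, X: np.ndarray) -> "SpectralDataset":
        """Same axis/labels/ids with a transformed absorbance matrix."""
        return replace(self, absorbance=np.asarray(X, dtype=float))


def normalize_label(raw: object) -> str:
    key = str(raw).strip().upper()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognised class label {raw!r} (expected POS/NEG or A/N)")
    return _LABEL_ALIASES[key]


def read_spectra_csv(path, label_column: str = LABEL_COLUMN) -> SpectralDataset:
    """Read a labelled spectral matrix from CSV.

    Schema: ``sample_id`` column, a label column, and one numeric
    wavenumber header (cm^-1) per remaining column. Wavenumbers may appear
    in either order; the result is always ascending.
    """
    df = pd.read_csv(path, dtype={SAMPLE_ID_COLUMN: str})
    if SAMPLE_ID_COLUMN not in df.columns:
        raise ValueError(f"CSV must contain a {SAMPLE_ID_COLUMN!r} column")
    if label_column not in df.columns:
        raise ValueError(f"CSV must contain the label column {label_column!r}")

    spec_cols = [c for c in df.columns if c not in (SAMPLE_ID_COLUMN, label_column)]
    if len(spec_cols) < 3:
        raise ValueError("CSV must contain at least 3 wavenumber columns")
    try:
        wn = np.array([float(c) for c in spec_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber column header: {exc}") from None

    sample_ids = df[SAMPLE_ID_COLUMN].to_numpy(dtype=object)
    dup = pd.Series(sample_ids).duplicated()
    if dup.any():
        raise ValueError(f"duplicate sample id {sample_ids[dup.idxmax()]!r}")
    labels = np.array([normalize_label(v) for v in df[label_column]], dtype=object)

    X = df[spec_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise ValueError(
            f"missing value at row {sample_ids[i]!r}, column {spec_cols[j]!r}"
        )
    order = np.argsort(wn, kind="stable")
    return SpectralDataset(wn[order], X[:, order], labels, sample_ids)


def write_spectra_csv(dataset: SpectralDataset, path):
    """Write a dataset to CSV readable by :func:`read_spectra_csv`.

    Floats are written with ``repr`` precision, so one write/read cycle
    perturbs absorbance by no more than float round-off.
    """
    dataset.validate()
    df = pd.DataFrame(dataset.absorbance,
                      columns=[repr(float(w)) for w in dataset.wavenumbers])
    df.insert(0, LABEL_COLUMN, dataset.labels)
    df.insert(0, SAMPLE_ID_COLUMN, dataset.sample_ids)
    df.to_csv(path, index=False)
    return path


def trim_wavenumbers(dataset: SpectralDataset, low: float, high: float) -> SpectralDataset:
    """Restrict to the closed wavenumber interval [low, high] cm^-1.

    The high-wavenumber end of an FT-NIR scan often carries little signal;
    dropping it (e.g. keeping 4000-9000 cm^-1 of a 4000-12000 scan) is a
    standard first step. Sample rows are unchanged.
    """
    if not low < high:
        raise ValueError(f"require low < high, got [{low}, {high}]")
    keep = (dataset.wavenumbers >= low) & (dataset.wavenumbers <= high)
    if not keep.any():
        raise ValueError(f"no wavenumbers inside [{low}, {high}]")
    return replace(
        dataset,
        wavenumbers=dataset.wavenumbers[keep],
        absorbance=dataset.absorbance[:, keep],
    )
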