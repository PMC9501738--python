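"""The samples-x-bands spectra table shared by every stage of the pipeline."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectraTable", "write_spectra_csv", "read_spectra_csv"]


@dataclass
class SpectraTable:
    """Spectra as rows over a shared wavelength axis, with optional labels.

    ``provenance`` tags each row's origin, e.g. the (row, col) pixel a
    spectrum was lifted from, or a synthetic sample identifier.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray | None = None
    provenance: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("columns of X must match the wavelength axis")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("one label per row required")
            if len(self.labels) and self.labels.min() < 0:
                raise ValueError("labels must be non-negative class ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise ValueError("table has no labels")
        return int(self.labels.max()) + 1


def write_spectra_csv(table: SpectraTable, path: str | os.PathLike) -> None:
    """Write a delimited table: header 'label' + wavelengths, one row/sample."""
    labels = table.labels if table.labels is not None else np.full(table.n_samples, -1)
    df = pd.DataFrame(table.X, columns=[f"{w:.6g}" for w in table.wavelengths])
    df.insert(0, "label", labels)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | os.PathLike) -> SpectraTable:
    df = pd.read_csv(path)
    if df.columns[0] != "label":
        raise ValueError("first column must be 'label'")
    labels = df["label"].to_numpy(dtype=int)
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    return SpectraTable(X, wavelengths, labels=None if (labels < 0).all() else labels)
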