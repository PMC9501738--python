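"""PCA for cluster-trend exploration of spectra tables.

Spectra are mean-centered but not variance-scaled, the usual convention
for reflectance data where the bands share units. The loadings' sign is
fixed (largest-magnitude element positive) so repeated fits are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .tables import SpectraTable

__all__ = ["PCAResult", "fit_pca", "cumulative_variance"]


@dataclass
class PCAResult:
    scores: np.ndarray        # samples x k
    loadings: np.ndarray      # bands x k, columns orthonormal
    explained_pct: np.ndarray  # k percentages, non-increasing
    mean: np.ndarray          # band-wise centering vector


def fit_pca(table: SpectraTable, k: int) -> PCAResult:
    """Centered (not scaled) PCA with ``k`` components.

    ``explained_pct`` are eigenvalue shares of total variance in percent;
    ``scores = (X - mean) @ loadings``.
    """
    n, p = table.X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside [1, min(samples-1, bands)={min(n - 1, p)}]")

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(table.X)
    loadings = pca.components_.T.copy()

    # deterministic sign: largest-|.| loading element positive per component
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_pct=pca.explained_variance_ratio_ * 100.0,
        mean=pca.mean_,
    )


def cumulative_variance(result: PCAResult, m: int) -> float:
    """Percent of total variance captured by the first ``m`` components."""
    if not 1 <= m <= len(result.explained_pct):
        raise ValueError(f"m={m} outside [1, {len(result.explained_pct)}]")
    return float(result.explained_pct[:m].sum())
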