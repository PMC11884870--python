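"""PCA dimensionality reduction of each feature block before the sparse CCA.

Reduction prevents an overdetermined, rank-deficient canonical solution:
the games block is reduced to 30 components and each brain block to 60 by
default, with a robustness mode re-running the analysis at 70 and 80.
Columns are z-scored by default before the SVD so mixed units (mm, ratios,
graph indices) contribute comparably; the centered (optionally scaled)
matrix is decomposed by singular value decomposition for numerical
stability, and component signs are fixed deterministically (the
largest-magnitude loading of each component is made positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCModel", "pca", "DEFAULT_K"]

DEFAULT_K = {"games": 30, "brain": 60}
ROBUSTNESS_K = (70, 80)


@dataclass
class PCModel:
    scores: pd.DataFrame  # participants x K
    loadings: pd.DataFrame  # variables x K
    variance_explained: np.ndarray  # per-component fraction of total variance
    K: int
    mean: np.ndarray
    scale: np.ndarray | None

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_explained.sum())


def pca(X: pd.DataFrame | np.ndarray, K: int, *, standardize: bool = True) -> PCModel:
    """Top-K principal components of a participants x variables matrix.

    ``K`` must not exceed min(n - 1, p). Constant columns are rejected when
    ``standardize`` is on (their z-score is undefined).
    """
    if isinstance(X, pd.DataFrame):
        index, columns, A = X.index, X.columns, X.to_numpy(float)
    else:
        A = np.asarray(X, dtype=float)
        index = pd.RangeIndex(A.shape[0])
        columns = pd.RangeIndex(A.shape[1])
    n, p = A.shape
    if not (1 <= K <= min(n - 1, p)):
        raise ValueError(f"K={K} outside [1, min(n-1, p)]={min(n - 1, p)}")
    mean = A.mean(axis=0)
    A = A - mean
    scale = None
    if standardize:
        scale = A.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = [str(columns[i]) for i in np.nonzero(scale == 0)[0][:5]]
            raise ValueError(f"constant columns cannot be standardized: {bad}")
        A = A / scale

    model = PCA(n_components=K, svd_solver="full")
    scores = model.fit_transform(A)
    components = model.components_  # K x p right singular directions
    # Deterministic sign: largest-|loading| entry of each component positive.
    for k in range(K):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    pcs = [f"PC{k + 1}" for k in range(K)]
    return PCModel(
        scores=pd.DataFrame(scores, index=index, columns=pcs),
        loadings=pd.DataFrame(components.T, index=columns, columns=pcs),
        variance_explained=model.explained_variance_ratio_.copy(),
        K=K,
        mean=mean,
        scale=scale,
    )
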