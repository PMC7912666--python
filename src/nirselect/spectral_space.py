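"""Principal-component score space and Mahalanobis distances.

All sample-selection distances live in a k-component PCA score space whose
scores are standardized by the square root of each component's score
variance.  In that space the global H of a sample is its mean squared
standardized score, scaled so the population mean of H on the training set
is (n-1)/n (hence approximately 1) and the conventional H > 3 rule flags
spectral outliers; the neighbourhood distance NH is the same quadratic form
between two samples.

Score variances use the sample (1/(n-1)) convention, which makes the
mean-H identity exact.  PCA is computed by singular value decomposition with
a deterministic sign convention: the largest-magnitude element of each
loading vector is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .synthetic import SpectralDataset


@dataclass
class PCAModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # bands x k, orthonormal columns
    eigenvalues: np.ndarray  # score variances, non-increasing, > 0
    k: int
    explained_fraction: float
    n_train: int

    def transform(self, spectra: np.ndarray, sample_ids=None) -> "ScoreMatrix":
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        raw = (X - self.mean_spectrum) @ self.loadings
        std = raw / np.sqrt(self.eigenvalues)
        if sample_ids is None:
            sample_ids = list(range(X.shape[0]))
        return ScoreMatrix(sample_ids=list(sample_ids), scores=std, k=self.k)


@dataclass
class ScoreMatrix:
    """Standardized scores: samples x k, column variances ~ 1 on training."""

    sample_ids: list
    scores: np.ndarray
    k: int


def fit_pca(
    spectra: np.ndarray,
    target_explained: float | None = None,
    fixed_k: int | None = None,
) -> PCAModel:
    """Fit the score space; choose k as the smallest count reaching
    ``target_explained`` of the total variance, or use ``fixed_k``."""
    if (target_explained is None) == (fixed_k is None):
        raise ValueError("give exactly one of target_explained / fixed_k")
    X = np.asarray(spectra, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    positive = variances > max(1e-12 * total, 1e-300)
    variances = variances[positive]
    vt = vt[positive]
    if fixed_k is not None:
        if fixed_k < 1 or fixed_k > len(variances):
            raise ValueError(f"fixed_k={fixed_k} exceeds the rank {len(variances)}")
        k = fixed_k
    else:
        if not (0 < target_explained <= 1):
            raise ValueError("target_explained must be in (0, 1]")
        cum = np.cumsum(variances) / total
        k = int(np.searchsorted(cum, target_explained - 1e-12) + 1)
        k = min(k, len(variances))
    loadings = vt[:k].T
    # deterministic sign: largest-magnitude element of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    explained = float(variances[:k].sum() / total)
    return PCAModel(
        mean_spectrum=mean,
        loadings=loadings,
        eigenvalues=variances[:k],
        k=k,
        explained_fraction=explained,
        n_train=n,
    )


def global_h(model: PCAModel, scores: ScoreMatrix) -> np.ndarray:
    """H(x) = (1/k) sum_j standardized_score_j(x)^2.

    On the training population mean(H) = (n-1)/n exactly; samples with
    H above 3 are the conventional spectral outliers.
    """
    if scores.k != model.k:
        raise ValueError("score matrix does not match the model dimension")
    return (scores.scores**2).sum(axis=1) / model.k


def nh_matrix(scores: ScoreMatrix) -> np.ndarray:
    """NH(a, b) = (1/k) sum_j (std_score_j(a) - std_score_j(b))^2."""
    if scores.scores.shape[0] < 2:
        raise ValueError("NH needs at least 2 samples")
    return squareform(pdist(scores.scores, metric="sqeuclidean")) / scores.k


def remove_spectral_outliers(
    dataset: SpectralDataset, model: PCAModel, threshold: float = 3.0
) -> tuple[SpectralDataset, list]:
    """Single-pass removal of samples with H > threshold (no refit)."""
    scores = model.transform(dataset.spectra, dataset.sample_ids)
    h = global_h(model, scores)
    keep = np.flatnonzero(h <= threshold)
    removed = [dataset.sample_ids[i] for i in np.flatnonzero(h > threshold)]
    return dataset.subset(keep), removed


def scores_to_frame(model: PCAModel, scores: ScoreMatrix) -> pd.DataFrame:
    """Tabular export: id, PC1..PCk (standardized), H."""
    df = pd.DataFrame(
        scores.scores, columns=[f"PC{j + 1}" for j in range(scores.k)]
    )
    df.insert(0, "id", scores.sample_ids)
    df["H"] = global_h(model, scores)
    return df


__all__ = [
    "PCAModel",
    "ScoreMatrix",
    "fit_pca",
    "global_h",
    "nh_matrix",
    "remove_spectral_outliers",
    "scores_to_frame",
]
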