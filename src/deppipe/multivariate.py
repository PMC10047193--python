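"""Sample-level quality control: similarity, hierarchical clustering,
k-means and PCA.

Samples are points in protein space (one coordinate per protein, log
abundance). Similarity is Euclidean distance or Pearson correlation
between sample vectors; hierarchical clustering runs on the distance
matrix (complete linkage by default); k-means (k = 2, Euclidean, seeded,
10 restarts) and PCA on the centered sample x protein matrix give the
ordination view. Protein-level distances are available via
``axis="proteins"`` for heatmap use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .datamodel import AbundanceDataset


@dataclass
class SampleOrdination:
    """PCA scores, k-means labels and similarity matrices for the samples."""

    sample_ids: list[str]
    pc_scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    kmeans_labels: np.ndarray
    distance_matrix: np.ndarray
    correlation_matrix: np.ndarray
    dendrogram: np.ndarray  # scipy linkage matrix


def _sample_matrix(dataset: AbundanceDataset, axis: str) -> np.ndarray:
    if dataset.mask.any():
        raise ValueError("dataset contains missing values; impute first")
    if axis == "samples":
        return dataset.values.T  # rows = samples
    if axis == "proteins":
        return dataset.values
    raise ValueError(f"unknown axis {axis!r}")


def sample_similarity(
    dataset: AbundanceDataset, method: str = "euclidean", axis: str = "samples"
) -> np.ndarray:
    """Pairwise Euclidean distance or Pearson correlation matrix.

    ``axis="samples"`` (default) compares sample columns as vectors over
    proteins; ``axis="proteins"`` compares protein rows.
    """
    x = _sample_matrix(dataset, axis)
    if method == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if method == "pearson":
        sds = x.std(axis=1)
        if (sds == 0).any():
            raise ValueError("zero-variance vector: Pearson correlation undefined")
        return np.corrcoef(x)
    raise ValueError(f"unknown method {method!r}")


def hierarchical_clustering(
    distance_matrix: np.ndarray, linkage: str = "complete"
) -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns the scipy linkage matrix (merge tree with heights).
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    return hierarchy.linkage(squareform(d, checks=False), method=linkage)


def kmeans_pca(
    dataset: AbundanceDataset,
    k: int = 2,
    n_components: int = 2,
    seed: int = 0,
    linkage: str = "complete",
) -> SampleOrdination:
    """k-means then PCA on the sample x protein matrix.

    k-means uses Euclidean distance with 10 seeded restarts (best
    within-cluster sum of squares wins); PCA is on the mean-centered,
    unscaled matrix, as all proteins share the log-abundance scale.
    """
    x = _sample_matrix(dataset, "samples")
    n_samples = x.shape[0]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds number of samples ({n_samples})")
    n_components = min(n_components, n_samples, x.shape[1])

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x)

    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(x)

    dist = sample_similarity(dataset, "euclidean")
    corr = sample_similarity(dataset, "pearson")
    return SampleOrdination(
        sample_ids=list(dataset.sample_ids),
        pc_scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
        kmeans_labels=labels,
        distance_matrix=dist,
        correlation_matrix=corr,
        dendrogram=hierarchical_clustering(dist, linkage=linkage),
    )
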