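"""Embedding evaluation: baselines, projection, clustering and NMI.

The central question is whether driver mutations (genes that recur
across tumours and push carcinogenesis) separate from passenger
mutations (sporadic, non-causal) in the learned vector space.  The
package quantifies this by k-means clustering the driver/passenger
vectors and scoring the clustering against the labels with normalized
mutual information,

    NMI(Omega, C) = MI(Omega, C) / ((H(Omega) + H(C)) / 2)

with natural logarithms (NMI is base-invariant).  A sparse binary
gene-by-sample incidence matrix serves as the no-learning baseline
representation, and 2-component PCA provides the visual check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import MutationProfileSet, Partition
from .exceptions import ConfigurationError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


def binary_matrix(
    profiles: MutationProfileSet, vocab: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Gene x sample 0/1 incidence matrix.

    Entry (g, s) is 1 iff gene g is mutated in sample s.  Row order
    follows ``vocab`` when given (genes never observed get zero rows
    only if explicitly listed); otherwise rows are the observed genes in
    count-descending, then lexicographic, order.  Returns
    ``(matrix, gene_order, sample_order)``.
    """
    if vocab is None:
        counts = profiles.gene_counts()
        vocab = [g for g, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    else:
        vocab = list(vocab)
    row = {g: i for i, g in enumerate(vocab)}
    mat = np.zeros((len(vocab), len(profiles)), dtype=np.int8)
    for s, (_, genes) in enumerate(profiles):
        for g in genes:
            if g in row:
                mat[row[g], s] = 1
    return mat, vocab, profiles.sample_ids


@dataclass
class ProjectionResult:
    """2-D (or k-D) PCA projection with per-component variance shares."""

    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray


def pca_project(vectors: np.ndarray, n_components: int = 2) -> ProjectionResult:
    """Mean-centered PCA with a deterministic sign convention.

    Each principal axis is flipped, if needed, so that its
    largest-magnitude loading is positive; this removes the sign
    ambiguity of eigenvectors and makes projections reproducible.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] <= n_components:
        raise ConfigurationError(
            f"need more than {n_components} rows for a {n_components}-component PCA"
        )
    if np.allclose(X, X[0]):
        raise DegenerateInputError("zero-variance input: all rows identical")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    components = pca.components_.copy()
    for c in range(n_components):
        lead = np.argmax(np.abs(components[c]))
        if components[c, lead] < 0:
            components[c] = -components[c]
            coords[:, c] = -coords[:, c]
    return ProjectionResult(coords, pca.explained_variance_ratio_.copy(), components)


def kmeans_cluster(
    vectors: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    items: Sequence[object] | None = None,
) -> Partition:
    """Lloyd k-means (k-means++ seeding, best inertia of ``n_init`` runs).

    Clustering runs on the full-dimensional vectors — dimensionality
    reduction is for display only.  ``items`` names the rows (defaults
    to row indices).
    """
    X = np.asarray(vectors, dtype=np.float64)
    if k > X.shape[0]:
        raise ConfigurationError(f"k={k} exceeds the {X.shape[0]} available points")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    if items is None:
        items = list(range(X.shape[0]))
    if len(items) != X.shape[0]:
        raise ValidationError("items length != number of vectors")
    return Partition(dict(zip(items, (int(l) for l in labels))))


def entropy(partition: Partition) -> float:
    """Shannon entropy of the block-size distribution (natural log)."""
    sizes = partition.block_sizes().astype(np.float64)
    p = sizes / sizes.sum()
    return float(-(p * np.log(p)).sum())


def _check_same_items(omega: Partition, classes: Partition) -> None:
    if omega.items != classes.items:
        raise ValidationError("partitions are over different item sets")


def mutual_information(omega: Partition, classes: Partition) -> float:
    """MI between a clustering and a labelling over the same items.

    MI = sum_ij p(w_i, c_j) log[p(w_i, c_j) / (p(w_i) p(c_j))], natural
    log, with 0 log 0 = 0.
    """
    _check_same_items(omega, classes)
    n = len(omega)
    joint: dict[tuple[int, int], int] = {}
    for item, b in omega.assignment.items():
        key = (b, classes.assignment[item])
        joint[key] = joint.get(key, 0) + 1
    p_omega: dict[int, float] = {}
    p_class: dict[int, float] = {}
    for (b, c), cnt in joint.items():
        p_omega[b] = p_omega.get(b, 0.0) + cnt / n
        p_class[c] = p_class.get(c, 0.0) + cnt / n
    mi = 0.0
    for (b, c), cnt in joint.items():
        p = cnt / n
        mi += p * math.log(p / (p_omega[b] * p_class[c]))
    return max(0.0, mi)  # clip -0.0 / rounding noise


def nmi(omega: Partition, classes: Partition) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    Symmetric and in [0, 1].  If both partitions are single-block (both
    entropies zero) they are identical and 1.0 is returned with a
    warning — the measure is degenerate there.
    """
    _check_same_items(omega, classes)
    h1, h2 = entropy(omega), entropy(classes)
    if h1 == 0.0 and h2 == 0.0:
        logger.warning("NMI of two single-block partitions is degenerate; returning 1.0")
        return 1.0
    return mutual_information(omega, classes) / ((h1 + h2) / 2.0)
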