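"""Prototype streamline selection via distance maps and streamline affinity.

The prototype of a bundle is the streamline most representative of its
spatial trajectory: pairwise streamline distances (symmetrized mean
closest-point distance) are converted to affinities with a Gaussian
kernel a(i,j) = exp(-d(i,j)^2 / sigma^2), and the streamline with the
largest affinity row sum is selected.  Selection is deliberately not
based on streamline length, which is vulnerable to measurement noise.

Highly dispersed bundles can carry more than one distinct trajectory; an
optional multi-prototype mode partitions the affinity matrix spectrally
(cluster count by eigengap) and returns one prototype per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from peritract.matching import Bundle

__all__ = [
    "AffinityMatrix",
    "pairwise_distances",
    "affinity",
    "select_prototype",
    "select_prototypes",
]

DEFAULT_SIGMA_AFF = 5.0  # mm, on the order of a bundle's width


@dataclass
class AffinityMatrix:
    values: np.ndarray  # (n, n), symmetric, diagonal 1
    sigma_aff: float

    def __post_init__(self):
        v = self.values
        assert np.allclose(v, v.T, atol=1e-12)
        assert np.allclose(np.diag(v), 1.0)


def mean_closest_point_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrized mean closest-point distance between two polylines (mm).

    0.5 * [mean over points of p of the distance to the nearest point of q
    + the same with roles swapped].  This is the distance-map measure used
    for streamline clustering.
    """
    tp, tq = cKDTree(p), cKDTree(q)
    d_pq = tq.query(p)[0].mean()
    d_qp = tp.query(q)[0].mean()
    return 0.5 * float(d_pq + d_qp)


def pairwise_distances(bundle: Bundle) -> np.ndarray:
    """Full n x n matrix of symmetrized mean closest-point distances."""
    n = len(bundle)
    pts = [np.asarray(s.points) for s in bundle]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = mean_closest_point_distance(pts[i], pts[j])
    return out


def affinity(distances: np.ndarray, sigma_aff: float = DEFAULT_SIGMA_AFF) -> AffinityMatrix:
    """Gaussian streamline affinity a(i,j) = exp(-d^2 / sigma^2)."""
    if sigma_aff <= 0:
        raise ValueError("sigma_aff must be positive")
    d = np.asarray(distances, dtype=float)
    return AffinityMatrix(values=np.exp(-(d**2) / sigma_aff**2), sigma_aff=sigma_aff)


def _argmax_with_ties(scores: np.ndarray, lengths: np.ndarray, tol: float = 1e-12) -> int:
    best = scores.max()
    tied = np.flatnonzero(scores >= best - tol)
    if len(tied) == 1:
        return int(tied[0])
    # ties: prefer the longer streamline, then the lower index
    order = sorted(tied, key=lambda i: (-lengths[i], i))
    return int(order[0])


def select_prototype(bundle: Bundle, sigma_aff: float = DEFAULT_SIGMA_AFF) -> int:
    """Index of the streamline maximizing the affinity row sum."""
    if len(bundle) == 1:
        return 0
    aff = affinity(pairwise_distances(bundle), sigma_aff).values
    scores = aff.sum(axis=1)
    lengths = np.array([s.length for s in bundle])
    return _argmax_with_ties(scores, lengths)


def _eigengap_k(aff: np.ndarray, k_max: int) -> int:
    """Cluster count from the largest eigengap of the normalized affinity."""
    deg = aff.sum(axis=1)
    d_inv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    sym = d_inv[:, None] * aff * d_inv[None, :]
    w = np.sort(np.linalg.eigvalsh(sym))[::-1]
    k_max = min(k_max, len(w) - 1)
    gaps = w[:k_max] - w[1 : k_max + 1]
    return int(np.argmax(gaps)) + 1


def select_prototypes(bundle: Bundle, sigma_aff: float = DEFAULT_SIGMA_AFF,
                      k_max: int = 5, random_state: int = 0) -> list:
    """One prototype per trajectory cluster of a dispersed bundle.

    Spectral partitioning of the affinity matrix with the cluster count
    chosen by the eigengap heuristic; within each cluster the affinity
    row sum (restricted to the cluster) picks the prototype.  Returns a
    sorted list of streamline indices (length 1 for coherent bundles).
    """
    n = len(bundle)
    if n == 1:
        return [0]
    aff = affinity(pairwise_distances(bundle), sigma_aff).values
    k = _eigengap_k(aff, k_max)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        from sklearn.cluster import SpectralClustering

        sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                                random_state=random_state, assign_labels="discretize")
        labels = sc.fit_predict(aff)
    lengths = np.array([s.length for s in bundle])
    protos = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        scores = aff[np.ix_(idx, idx)].sum(axis=1)
        protos.append(int(idx[_argmax_with_ties(scores, lengths[idx])]))
    return sorted(protos)
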