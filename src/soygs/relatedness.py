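"""Genomic relatedness and population structure.

Kinship uses VanRaden's method 1: with W the column-centered dosage matrix
and p_k the allele frequency of marker k,

    K = W W' / (2 * sum_k p_k (1 - p_k)),

monomorphic markers excluded from numerator and denominator.  Population
structure is summarized by PCA of the column-standardized dosages; discrete
subpopulations come from k-means on the leading components with
silhouette-based choice of k -- a deterministic surrogate for Bayesian
admixture clustering that yields the discrete partition the downstream
training-set designs need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import GenotypeMatrix, PopulationPartition
from .errors import ConfigurationError, DataError

logger = logging.getLogger("soygs")


@dataclass
class KinshipMatrix:
    """n x n symmetric genomic relationship matrix."""

    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DataError("kinship matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("kinship matrix is not symmetric within 1e-10")


@dataclass
class PCAResult:
    sample_ids: np.ndarray
    scores: np.ndarray  # n x n_components
    explained_variance_ratio: np.ndarray


@dataclass
class ClusteringResult:
    """k-means structure assignment with its model-selection diagnostics."""

    partition: PopulationPartition
    selected_k: int
    silhouette_by_k: dict[int, float]
    weak_structure: bool


def _require_imputed(G: GenotypeMatrix, op: str) -> np.ndarray:
    if G.has_missing():
        raise DataError(f"{op} requires an imputed genotype matrix (no missing calls)")
    return G.dosages


def vanraden_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    D = _require_imputed(G, "vanraden_kinship")
    var = D.var(axis=0)
    poly = var > 0
    if not poly.any():
        raise DataError("all markers are monomorphic; kinship undefined")
    Dp = D[:, poly]
    p = Dp.mean(axis=0) / 2.0
    W = Dp - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0  # kill round-off asymmetry
    return KinshipMatrix(G.sample_ids, K)


def genotype_pca(G: GenotypeMatrix, n_components: int) -> PCAResult:
    """PCA of the column-standardized dosage matrix.

    Zero-variance markers are dropped before standardization.  Component
    signs are fixed by making each component's largest-magnitude marker
    loading positive, so scores are fully deterministic.
    """
    D = _require_imputed(G, "genotype_pca")
    n, m = D.shape
    if not 1 <= n_components < min(n, m):
        raise ConfigurationError("n_components must satisfy 1 <= c < min(n, m)")
    sd = D.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DataError("all markers monomorphic; PCA undefined")
    Z = (D[:, keep] - D[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return PCAResult(G.sample_ids, scores, pca.explained_variance_ratio_)


def ld_prune_adjacent(G: GenotypeMatrix, r2_max: float = 0.50) -> np.ndarray:
    """Greedy adjacent-LD pruning; returns retained marker IDs in map order.

    Per chromosome, left to right: keep the first marker; keep each later
    marker iff its squared Pearson correlation with the most recently KEPT
    marker is below ``r2_max``.  Zero-variance markers count as r^2 = 0
    (kept) and are logged.
    """
    if not 0 < r2_max <= 1:
        raise ConfigurationError("r2_max must lie in (0, 1]")
    D = _require_imputed(G, "ld_prune_adjacent")
    keep = np.zeros(G.n_markers, dtype=bool)
    n_zero_var = 0
    last_kept = -1
    for k in range(G.n_markers):
        if k == 0 or G.chrom[k] != G.chrom[k - 1]:
            keep[k] = True
            last_kept = k
            continue
        x, ref = D[:, k], D[:, last_kept]
        if x.std() == 0 or ref.std() == 0:
            r2 = 0.0
            if x.std() == 0:
                n_zero_var += 1
        else:
            r2 = float(np.corrcoef(x, ref)[0, 1]) ** 2
        if r2 < r2_max:
            keep[k] = True
            last_kept = k
    if n_zero_var:
        logger.info("ld_prune_adjacent: %d zero-variance markers treated as r2=0",
                    n_zero_var)
    return G.marker_ids[keep]


def cluster_subpopulations(
    scores: PCAResult | np.ndarray,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    n_init: int = 10,
    n_components: int = 10,
    weak_silhouette: float = 0.2,
    sample_ids: np.ndarray | None = None,
) -> ClusteringResult:
    """Discrete subpopulations via k-means on leading PCA scores.

    Runs k-means for every k in ``k_range`` (inclusive) on the first
    ``n_components`` (or fewer, if not available) score columns, picks the
    k with the best mean silhouette, and relabels groups by descending size
    (Gpop1 is the largest).  A best silhouette below ``weak_silhouette``
    flags weak structure.
    """
    if isinstance(scores, PCAResult):
        X = scores.scores
        ids = scores.sample_ids
    else:
        X = np.asarray(scores, dtype=float)
        if sample_ids is None:
            raise ConfigurationError("sample_ids required when passing a raw score array")
        ids = np.asarray(sample_ids, dtype=str)
    k_min, k_max = k_range
    if not 2 <= k_min <= k_max:
        raise ConfigurationError("k_range must satisfy 2 <= k_min <= k_max")
    n = X.shape[0]
    if n < k_max + 1:
        raise DataError(f"need more than {k_max} samples to cluster up to k={k_max}")
    X = X[:, : min(n_components, X.shape[1])]

    rng = np.random.SeedSequence(seed)
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k, child in zip(range(k_min, k_max + 1), rng.spawn(k_max - k_min + 1)):
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            random_state=int(child.generate_state(1)[0] % (2**31)),
        )
        lab = km.fit_predict(X)
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(X, lab)) if len(np.unique(lab)) > 1 else -1.0
    best_k = max(sil, key=lambda k: (sil[k], -k))
    raw = labels_by_k[best_k]

    # relabel by descending group size, ties broken by original label
    uniq, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((uniq, -counts))
    mapping = {int(uniq[i]): f"Gpop{rank + 1}" for rank, i in enumerate(order)}
    labels = np.array([mapping[int(v)] for v in raw])

    weak = sil[best_k] < weak_silhouette
    if weak:
        logger.warning(
            "cluster_subpopulations: weak structure (best silhouette %.3f at k=%d)",
            sil[best_k],
            best_k,
        )
    return ClusteringResult(
        partition=PopulationPartition(ids, labels, scheme="genetic"),
        selected_k=best_k,
        silhouette_by_k=sil,
        weak_structure=weak,
    )


__all__ = [
    "ClusteringResult",
    "KinshipMatrix",
    "PCAResult",
    "cluster_subpopulations",
    "genotype_pca",
    "ld_prune_adjacent",
    "vanraden_kinship",
]
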