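"""Base clustering methods applied to one EEG epoch.

Each single-trial epoch is treated as its own dataset: time points are the
observations and electrodes the features, so a cluster is a set of time points
sharing a quasi-stable scalp topography.  Nine methods are exposed through a
registry addressable by short name:

====  =============================================
KM    k-means
HC    hierarchical clustering (Ward)
FCM   fuzzy c-means (hard labels via max membership)
SOM   self-organizing map, 1 × K grid, batch trained
DSPC  spectral clustering on a diffusion-map embedding
MKM   modified k-means with polarity adjustment
SPC   spectral clustering (RBF affinity)
KMD   k-medoids
GMM   Gaussian mixture model (max responsibility)
====  =============================================

The methods that sklearn ships (KM, HC, SPC, GMM) are thin wrappers; the rest
are implemented here as small sklearn-compatible estimators (``fit`` /
``fit_predict`` / ``labels_``).  Stochastic methods take explicit seeds so the
whole pipeline is reproducible from a single master seed.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.mixture import GaussianMixture
from sklearn.utils import check_random_state

from .datamodel import Labeling

__all__ = [
    "METHOD_NAMES",
    "ClusteringError",
    "ModifiedKMeans",
    "FuzzyCMeans",
    "BatchSOM",
    "KMedoids",
    "DiffusionSpectral",
    "cluster_epoch",
    "modified_kmeans",
    "derive_seed",
    "STOCHASTIC_METHODS",
]

METHOD_NAMES = ("KM", "HC", "FCM", "SOM", "DSPC", "MKM", "SPC", "KMD", "GMM")

#: methods whose result depends on the seed (HC is fully deterministic)
STOCHASTIC_METHODS = frozenset(n for n in METHOD_NAMES if n != "HC")


class ClusteringError(RuntimeError):
    """A base method failed on this epoch (non-convergence, degeneracy...)."""


def derive_seed(master: int, *tokens) -> int:
    """Stable per-task seed below 2**31 from a master seed and context tokens.

    Used to give every (subject, condition, trial, method) clustering task its
    own reproducible stream.
    """
    key = ":".join(str(t) for t in (master, *tokens))
    return zlib.crc32(key.encode()) % (2**31 - 1)


# ---------------------------------------------------------------------------
# hand-rolled estimators
# ---------------------------------------------------------------------------


class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Topographic (microstate-style) k-means on unit-normalised maps.

    Assignment similarity is the cosine spatial correlation.  With
    ``polarity=True`` the sign is respected (an inverted map belongs to a
    different cluster) and centroids are normalised means; with
    ``polarity=False`` assignment uses ``|corr|`` and centroids are leading
    eigenvectors of the within-cluster scatter, reproducing the classical
    polarity-invariant variant.
    """

    def __init__(self, n_clusters=6, polarity=True, max_iter=100, n_init=2,
                 random_state=None):
        self.n_clusters = n_clusters
        self.polarity = polarity
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, F = X.shape
        K = self.n_clusters
        if n <= K:
            raise ClusteringError(f"need more than {K} observations, got {n}")
        norms = np.linalg.norm(X, axis=1)
        norms[norms == 0.0] = 1.0  # zero maps stay zero vectors
        U = X / norms[:, None]
        rng = check_random_state(self.random_state)

        best = None
        for _ in range(self.n_init):
            labels, score = self._single_run(U, K, rng)
            if best is None or score > best[1]:
                best = (labels, score)
        self.labels_ = best[0]
        self.inertia_ = -best[1]
        return self

    def _single_run(self, U, K, rng):
        n = U.shape[0]
        centers = U[rng.choice(n, size=K, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(self.max_iter):
            sim = U @ centers.T
            if not self.polarity:
                sim = np.abs(sim)
            new_labels = sim.argmax(axis=1)
            fit = sim[np.arange(n), new_labels]
            # re-seed any emptied cluster from the worst-fit point
            for k in range(K):
                if not np.any(new_labels == k):
                    worst = int(fit.argmin())
                    new_labels[worst] = k
                    fit[worst] = 1.0
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            for k in range(K):
                mem = U[labels == k]
                if self.polarity:
                    c = mem.mean(axis=0)
                else:
                    # leading eigenvector of the cluster scatter (sign-blind)
                    _, _, vt = np.linalg.svd(mem, full_matrices=False)
                    c = vt[0]
                nc = np.linalg.norm(c)
                centers[k] = c / nc if nc > 0 else mem[0]
        sim = U @ centers.T
        if not self.polarity:
            sim = np.abs(sim)
        score = float(sim[np.arange(n), labels].sum())
        return labels, score

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means (Bezdek), hard labels by maximum membership."""

    def __init__(self, n_clusters=6, m=2.0, max_iter=300, tol=1e-5,
                 random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        K = self.n_clusters
        rng = check_random_state(self.random_state)
        u = rng.dirichlet(np.ones(K), size=n)  # memberships, rows sum to 1
        for _ in range(self.max_iter):
            um = u**self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (self.m - 1.0))
            new_u = inv / inv.sum(axis=1, keepdims=True)
            if np.abs(new_u - u).max() < self.tol:
                u = new_u
                break
            u = new_u
        self.membership_ = u
        self.cluster_centers_ = centers
        self.labels_ = u.argmax(axis=1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class BatchSOM(ClusterMixin, BaseEstimator):
    """Self-organizing map on a 1 × K grid, batch training; units = clusters."""

    def __init__(self, n_clusters=6, n_epochs=20, random_state=None):
        self.n_clusters = n_clusters
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        K = self.n_clusters
        rng = check_random_state(self.random_state)
        W = X[rng.choice(n, size=K, replace=False)].copy()
        grid = np.arange(K, dtype=float)
        sigma0, sigma1 = max(K / 2.0, 1.0), 0.3
        for ep in range(self.n_epochs):
            sigma = sigma0 * (sigma1 / sigma0) ** (ep / max(self.n_epochs - 1, 1))
            d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
            bmu = d2.argmin(axis=1)
            # batch update: every unit pulls toward the neighbourhood-weighted mean
            h = np.exp(-((grid[:, None] - grid[bmu][None, :]) ** 2) / (2 * sigma**2))
            denom = h.sum(axis=1)
            W = np.where(denom[:, None] > 1e-12, (h @ X) / denom[:, None], W)
        d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        self.weights_ = W
        self.labels_ = d2.argmin(axis=1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class KMedoids(ClusterMixin, BaseEstimator):
    """Alternating k-medoids (Voronoi iteration) on Euclidean distances."""

    def __init__(self, n_clusters=6, max_iter=100, random_state=None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        K = self.n_clusters
        rng = check_random_state(self.random_state)
        D = squareform(pdist(X))
        medoids = rng.choice(n, size=K, replace=False)
        for _ in range(self.max_iter):
            labels = D[:, medoids].argmin(axis=1)
            new_medoids = medoids.copy()
            for k in range(K):
                mem = np.flatnonzero(labels == k)
                if mem.size == 0:
                    # re-seed from the point farthest from its medoid
                    worst = int(D[np.arange(n), medoids[labels]].argmax())
                    new_medoids[k] = worst
                    continue
                within = D[np.ix_(mem, mem)].sum(axis=1)
                new_medoids[k] = mem[within.argmin()]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                medoids = new_medoids
                break
            medoids = new_medoids
        self.medoid_indices_ = medoids
        self.labels_ = D[:, medoids].argmin(axis=1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class DiffusionSpectral(ClusterMixin, BaseEstimator):
    """Spectral clustering on a diffusion-map embedding.

    Gaussian kernel with bandwidth = median pairwise distance; the embedding
    uses the leading non-trivial eigenvectors of the normalised kernel scaled
    by their eigenvalues, followed by k-means.
    """

    def __init__(self, n_clusters=6, n_components=10, random_state=None):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        d = pdist(X)
        eps = np.median(d)
        if eps <= 0:
            raise ClusteringError("degenerate data: zero median pairwise distance")
        W = np.exp(-squareform(d) ** 2 / (2 * eps**2))
        deg = W.sum(axis=1)
        Dm12 = 1.0 / np.sqrt(deg)
        A = Dm12[:, None] * W * Dm12[None, :]
        A = (A + A.T) / 2.0
        ncomp = min(self.n_components, n - 2)
        if n > 200:
            from scipy.sparse.linalg import eigsh
            vals, vecs = eigsh(A, k=ncomp + 1, which="LA",
                               v0=np.full(n, 1.0 / np.sqrt(n)))
        else:
            vals, vecs = np.linalg.eigh(A)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        # map back to the row-stochastic operator's eigenvectors, drop trivial
        psi = Dm12[:, None] * vecs[:, 1 : ncomp + 1]
        emb = psi * vals[1 : ncomp + 1][None, :]
        km = KMeans(n_clusters=self.n_clusters, n_init=4,
                    random_state=self.random_state)
        self.labels_ = km.fit_predict(emb)
        self.embedding_ = emb
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# registry / dispatch
# ---------------------------------------------------------------------------


def _median_rbf_affinity(X: np.ndarray) -> np.ndarray:
    d = pdist(X)
    eps = np.median(d)
    if eps <= 0:
        raise ClusteringError("degenerate data: zero median pairwise distance")
    return np.exp(-squareform(d) ** 2 / (2 * eps**2))


def _make_estimator(name: str, K: int, seed: int | None):
    if name == "KM":
        return KMeans(n_clusters=K, n_init=2, random_state=seed)
    if name == "HC":
        return AgglomerativeClustering(n_clusters=K, linkage="ward")
    if name == "FCM":
        return FuzzyCMeans(n_clusters=K, random_state=seed)
    if name == "SOM":
        return BatchSOM(n_clusters=K, random_state=seed)
    if name == "DSPC":
        return DiffusionSpectral(n_clusters=K, random_state=seed)
    if name == "MKM":
        return ModifiedKMeans(n_clusters=K, polarity=True, random_state=seed)
    if name == "SPC":
        return SpectralClustering(n_clusters=K, affinity="precomputed",
                                  assign_labels="kmeans", random_state=seed)
    if name == "KMD":
        return KMedoids(n_clusters=K, random_state=seed)
    if name == "GMM":
        return GaussianMixture(n_components=K, covariance_type="full",
                               reg_covar=1e-4, n_init=1, max_iter=60,
                               random_state=seed)
    raise KeyError(f"unknown clustering method {name!r}; choose from {METHOD_NAMES}")


def cluster_epoch(data: np.ndarray, K: int, method: str,
                  seed: int | None = None, normalize: bool = False) -> Labeling:
    """Hard-cluster one epoch's time points into K topographic clusters.

    With ``normalize=True`` every time point's scalp map is scaled to unit L2
    norm first (standardization), so clusters group time points by
    topographic direction — polarity included — rather than by overall
    amplitude; without it, Euclidean methods tend to slice a large component
    into concentric amplitude shells.

    Raises :class:`ClusteringError` when the method fails on this epoch, so
    callers can drop the method and continue with the rest of the ensemble.
    """
    data = np.asarray(data, dtype=float)
    if normalize:
        norms = np.linalg.norm(data, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        data = data / norms
    if K < 2:
        raise ValueError("K must be at least 2")
    if data.shape[0] <= K:
        raise ValueError(f"need more than K={K} time points, got {data.shape[0]}")
    est = _make_estimator(method, K, seed)
    try:
        if method == "SPC":
            labels = est.fit_predict(_median_rbf_affinity(data))
        elif method == "GMM":
            labels = est.fit(data).predict(data)
        else:
            labels = est.fit_predict(data)
    except ClusteringError:
        raise
    except Exception as exc:  # noqa: BLE001 — any solver failure flags the method
        raise ClusteringError(f"{method} failed: {exc}") from exc
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ClusteringError(f"{method} collapsed to a single cluster")
    return Labeling(labels=labels - labels.min() + 1, K=int(labels.max() - labels.min() + 1))


def modified_kmeans(data: np.ndarray, K: int, polarity: bool = True,
                    seed: int | None = None) -> Labeling:
    """Convenience wrapper around :class:`ModifiedKMeans`."""
    est = ModifiedKMeans(n_clusters=K, polarity=polarity, random_state=seed)
    labels = est.fit_predict(np.asarray(data, dtype=float))
    return Labeling(labels=labels + 1, K=K)
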