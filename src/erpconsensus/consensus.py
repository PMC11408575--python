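"""Cluster-ensemble machinery: CSPA consensus and NMI-based selection.

Multi-set consensus clustering works at two levels.  Within one trial, the
labelings produced by several base methods are combined; across trials, the
per-trial consensus labelings of one subject/condition are combined again.
Both levels use the same selection rule: among the candidate partitions (the
inputs plus the CSPA consensus of the inputs), keep the one with maximum mean
normalized mutual information to all inputs, breaking ties toward CSPA.

CSPA builds the co-association matrix S (fraction of labelings that place two
time points in the same cluster) and partitions it.  The original literature
partitions the induced hypergraph with METIS; here the partitioner is
deterministic average-linkage agglomeration on the dissimilarity 1 − S, which
coincides with graph partitioning on block-structured co-association matrices
and removes a heavyweight dependency.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import normalized_mutual_info_score

from .clustering import ClusteringError, cluster_epoch, derive_seed
from .datamodel import Labeling

__all__ = [
    "coassociation",
    "cspa",
    "nmi",
    "select_consensus",
    "consensus_within_trial",
    "consensus_across_trials",
]


def _label_matrix(labelings: list[Labeling]) -> np.ndarray:
    if not labelings:
        raise ValueError("empty ensemble")
    n = labelings[0].n_time
    for l in labelings:
        if l.n_time != n:
            raise ValueError("all labelings must share one time axis")
    return np.stack([l.labels for l in labelings])


def coassociation(labelings: list[Labeling]) -> np.ndarray:
    """Co-association similarity: S_ij = fraction of labelings with i, j together."""
    L = _label_matrix(labelings)
    m, n = L.shape
    S = np.zeros((n, n))
    for row in L:
        S += row[:, None] == row[None, :]
    return S / m


def cspa(labelings: list[Labeling], K: int) -> Labeling:
    """CSPA consensus: partition the co-association matrix into K clusters."""
    S = coassociation(labelings)
    n = S.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of time points {n}")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    agg = AgglomerativeClustering(n_clusters=K, metric="precomputed",
                                  linkage="average")
    labels = agg.fit_predict(D)
    return Labeling(labels=labels + 1, K=K)


def nmi(l1: Labeling | np.ndarray, l2: Labeling | np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalisation) in [0, 1].

    A constant labeling has zero entropy; by convention its NMI with anything
    (including another constant labeling) is 0.
    """
    a = l1.labels if isinstance(l1, Labeling) else np.asarray(l1)
    b = l2.labels if isinstance(l2, Labeling) else np.asarray(l2)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def select_consensus(labelings: list[Labeling], K: int | None = None) -> Labeling:
    """Optimally combined clustering: argmax of mean NMI to all inputs.

    Candidates are the input labelings plus the CSPA consensus; ties (to within
    1e-12) go to the CSPA result.
    """
    if not labelings:
        raise ValueError("empty ensemble")
    if len(labelings) == 1:
        return labelings[0]
    if K is None:
        K = max(l.K for l in labelings)
    consensus = cspa(labelings, K)
    best_lab, best_score = None, -np.inf
    for cand in labelings:
        score = float(np.mean([nmi(cand, l) for l in labelings]))
        if score > best_score + 1e-12:
            best_lab, best_score = cand, score
    cspa_score = float(np.mean([nmi(consensus, l) for l in labelings]))
    if cspa_score >= best_score - 1e-12:
        return consensus
    return best_lab


def consensus_within_trial(
    data: np.ndarray,
    methods: list[str],
    K: int,
    master_seed: int = 0,
    context: tuple = (),
    normalize: bool = False,
) -> Labeling:
    """First-level consensus: run every base method on one epoch and combine.

    Methods that fail are dropped; if every method fails the trial is unusable
    and a :class:`ClusteringError` is raised.
    """
    labelings: list[Labeling] = []
    for m in methods:
        seed = derive_seed(master_seed, *context, m)
        try:
            labelings.append(cluster_epoch(data, K, m, seed=seed,
                                           normalize=normalize))
        except ClusteringError:
            continue
    if not labelings:
        raise ClusteringError("all base methods failed on this trial")
    return select_consensus(labelings, K)


def consensus_across_trials(trial_labelings: list[Labeling], K: int) -> Labeling:
    """Second-level consensus across the per-trial labelings of one subject."""
    if not trial_labelings:
        raise ValueError("no trial labelings to combine")
    return select_consensus(trial_labelings, K)
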