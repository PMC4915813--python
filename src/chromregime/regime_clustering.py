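"""Chromatin-regime clustering of peak-centred signal matrices.

Peaks are partitioned by k-means (two centres by default) on the
concatenated multi-track matrix, then ordered for display first by cluster
and second by peak score (descending), mirroring the usual stacked-heatmap
layout. Cluster ids are canonicalized by descending cluster size so that
repeated runs label the larger regime 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .signal_matrix import SignalMatrix


@dataclass
class ClusterResult:
    """k-means partition of peaks: labels, centres, display order, inertia."""

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    seed: int
    order: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def kmeans_cluster(
    combined: np.ndarray, k: int = 2, seed: int = 0, restarts: int = 10
) -> ClusterResult:
    """Cluster peaks with k-means++ (best inertia of ``restarts`` runs).

    Deterministic given ``seed``. Cluster ids are relabelled by descending
    cluster size (ties broken by the original id).
    """
    combined = np.asarray(combined, dtype=float)
    if combined.ndim != 2:
        raise ValueError("combined matrix must be 2-D")
    if combined.shape[0] < k:
        raise ValueError(f"{combined.shape[0]} rows cannot form {k} clusters")
    model = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts, random_state=seed
    )
    raw = model.fit_predict(combined)
    sizes = np.bincount(raw, minlength=k)
    by_size = np.argsort(-sizes, kind="stable")  # old id at new rank
    relabel = np.empty(k, dtype=int)
    relabel[by_size] = np.arange(k)
    return ClusterResult(
        labels=relabel[raw],
        centers=model.cluster_centers_[by_size],
        inertia=float(model.inertia_),
        seed=seed,
    )


def order_peaks(result: ClusterResult, scores: Sequence[float]) -> np.ndarray:
    """Display permutation: cluster id ascending, peak score descending.

    The sort is stable, so equal (cluster, score) pairs keep input order.
    The permutation is stored on ``result`` and returned.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != result.labels.shape[0]:
        raise ValueError(
            f"{scores.shape[0]} scores for {result.labels.shape[0]} peaks"
        )
    # lexsort: last key is primary; stable, so ties preserve input order.
    order = np.lexsort((-scores, result.labels))
    result.order = order
    return order


def cluster_profiles(
    matrices: Sequence[SignalMatrix], labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-track mean signal profile of each cluster (k x n_bins arrays).

    An empty cluster yields a zero profile and a warning.
    """
    labels = np.asarray(labels)
    k = int(labels.max()) + 1 if labels.size else 0
    profiles: dict[str, np.ndarray] = {}
    for m in matrices:
        if m.values.shape[0] != labels.shape[0]:
            raise ValueError(
                f"track {m.track!r}: {m.values.shape[0]} rows for "
                f"{labels.shape[0]} labels"
            )
        out = np.zeros((k, m.values.shape[1]))
        for c in range(k):
            members = labels == c
            if members.any():
                out[c] = m.values[members].mean(axis=0)
            else:
                warnings.warn(
                    f"cluster {c} is empty; zero profile emitted",
                    RuntimeWarning,
                    stacklevel=2,
                )
        profiles[m.track] = out
    return profiles
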