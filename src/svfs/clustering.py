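"""Feature clustering from the thresholded signature matrix.

Features whose columns are linearly dependent show up as nonzero off-diagonal
entries of the signature matrix.  Zeroing entries below a mean-scaled cutoff
(``Th_red``) removes the weak incidental correlations of real data, and the
connected components of the remaining graph — enumerated by a deterministic
breadth-first search — are the feature clusters.  Oversized clusters are
split into relevance-ordered chunks of at most ``alpha`` members.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .exceptions import InputError
from .linalg import SignatureMatrix

__all__ = [
    "ClusterPartition",
    "threshold_signature",
    "connected_components",
    "split_clusters",
    "edge_list",
]


@dataclass(frozen=True)
class ClusterPartition:
    """Disjoint ordered clusters of feature indices covering all features."""

    clusters: tuple[tuple[int, ...], ...]
    n_features: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if not c:
                raise InputError("empty cluster in partition")
            if seen & set(c):
                raise InputError("clusters are not disjoint")
            seen |= set(c)
        if seen != set(range(self.n_features)):
            raise InputError(
                f"partition covers {len(seen)} of {self.n_features} features"
            )

    def __len__(self) -> int:
        return len(self.clusters)

    def multi_member(self) -> list[tuple[int, ...]]:
        return [c for c in self.clusters if len(c) > 1]


def threshold_signature(S: SignatureMatrix, th_red: float = 4.0) -> sp.csr_matrix:
    """Boolean adjacency: edge (i, j) iff ``|S_ij|`` reaches the mean-scaled
    cutoff ``mean(|off-diagonal S|) * th_red`` (and is nonzero).

    The diagonal never contributes.  Returned matrix is symmetric CSR.
    """
    if th_red < 0:
        raise InputError(f"th_red must be >= 0, got {th_red}")
    A = np.abs(S.S.copy())
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    cutoff = 0.0
    if n > 1:
        cutoff = float(A.sum() / (n * (n - 1))) * th_red
    mask = (A >= cutoff) & (A > 0.0)
    np.fill_diagonal(mask, False)
    return sp.csr_matrix(mask)


def connected_components(
    adjacency: sp.spmatrix | np.ndarray, n_features: int
) -> ClusterPartition:
    """Clusters as BFS connected components, fully deterministic.

    BFS starts from the lowest-index unvisited feature; neighbor queues are
    processed in ascending index order; members are listed in visit order;
    components are emitted in order of their smallest member.
    """
    adj = sp.csr_matrix(adjacency)
    if adj.shape != (n_features, n_features):
        raise InputError(
            f"adjacency shape {adj.shape} does not match n_features={n_features}"
        )
    if (adj != adj.T).nnz:
        raise InputError("adjacency must be symmetric")
    visited = np.zeros(n_features, dtype=bool)
    clusters: list[tuple[int, ...]] = []
    for root in range(n_features):
        if visited[root]:
            continue
        visited[root] = True
        order = [root]
        queue = deque([root])
        while queue:
            u = queue.popleft()
            row = adj.indices[adj.indptr[u]:adj.indptr[u + 1]]
            for v in np.sort(row):
                if not visited[v]:
                    visited[v] = True
                    order.append(int(v))
                    queue.append(int(v))
        clusters.append(tuple(order))
    return ClusterPartition(clusters=tuple(clusters), n_features=n_features)


def split_clusters(
    partition: ClusterPartition,
    relevance_scores: Mapping[int, float] | np.ndarray,
    alpha: int = 50,
) -> ClusterPartition:
    """Split clusters larger than ``alpha`` into consecutive chunks of at
    most ``alpha`` members, ordered by descending relevance score (ties by
    ascending feature index)."""
    if alpha < 1:
        raise InputError(f"alpha must be >= 1, got {alpha}")
    scores = _score_lookup(relevance_scores)
    out: list[tuple[int, ...]] = []
    for cluster in partition.clusters:
        missing = [i for i in cluster if i not in scores]
        if missing:
            raise InputError(f"no relevance score for features {missing}")
        if len(cluster) <= alpha:
            out.append(cluster)
            continue
        ranked = sorted(cluster, key=lambda i: (-scores[i], i))
        for start in range(0, len(ranked), alpha):
            out.append(tuple(ranked[start:start + alpha]))
    return ClusterPartition(clusters=tuple(out), n_features=partition.n_features)


def _score_lookup(scores: Mapping[int, float] | np.ndarray) -> dict[int, float]:
    if isinstance(scores, Mapping):
        return {int(k): float(v) for k, v in scores.items()}
    arr = np.asarray(scores, dtype=float).ravel()
    return {i: float(v) for i, v in enumerate(arr)}


def edge_list(
    S: SignatureMatrix, adjacency: sp.spmatrix
) -> Iterable[tuple[int, int, float]]:
    """Yield (i, j, S_ij) for each undirected edge, i < j, for export."""
    coo = sp.coo_matrix(sp.triu(adjacency, k=1))
    for i, j in zip(coo.row, coo.col):
        yield int(i), int(j), float(S.S[i, j])
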