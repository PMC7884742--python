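"""Per-cluster representative choice by mutual information with the label.

All features in one cluster are linearly redundant, so a single
representative suffices.  Candidates are the ``beta`` members with the
highest relevance score; among them the one sharing the most information
with the class label wins.  Information quantities use the plug-in
(histogram) estimators in bits:

    H(Y)    = -sum_y p(y) log2 p(y)
    H(Y|X)  = -sum_x p(x) sum_y p(y|x) log2 p(y|x)
    I(X;Y)  = H(Y) - H(Y|X)

Continuous features are discretized into equal-width bins before estimation
("sturges" policy: ceil(log2 m) + 1 bins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .exceptions import InputError
from .relevance import LabeledDataset, RelevanceReport
from .clustering import ClusterPartition

__all__ = [
    "SVFSParams",
    "SelectionResult",
    "entropy",
    "mutual_information",
    "discretize",
    "rank_candidates",
    "select_representatives",
]


@dataclass(frozen=True)
class SVFSParams:
    """Tunable parameters of the selection pipeline.

    k: number of features to select (list is MI-descending, truncated to k).
    th_irr: soft threshold of both irrelevance-filter steps (mean-scaled).
    th_red: soft threshold zeroing weak signature entries before clustering
        (4 works well for expression data; 7 for image data).
    alpha: maximum cluster size after splitting.
    beta: relevance-ranked candidates per (sub-)cluster entering the MI race.
    mi_bins: equal-width bin count for MI, or "sturges".
    """

    k: int = 50
    th_irr: float = 3.0
    th_red: float = 4.0
    alpha: int = 50
    beta: int = 5
    mi_bins: Union[int, str] = "sturges"
    sv_tolerance: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError(f"k must be >= 1, got {self.k}")
        if self.alpha < 1:
            raise InputError(f"alpha must be >= 1, got {self.alpha}")
        if not 1 <= self.beta <= self.alpha:
            raise InputError(
                f"beta must be in [1, alpha={self.alpha}], got {self.beta}"
            )
        if self.th_irr < 0 or self.th_red < 0:
            raise InputError("thresholds must be >= 0")
        if isinstance(self.mi_bins, str):
            if self.mi_bins != "sturges":
                raise InputError(f"unknown mi_bins policy {self.mi_bins!r}")
        elif self.mi_bins < 1:
            raise InputError(f"mi_bins must be >= 1, got {self.mi_bins}")


@dataclass(frozen=True)
class SelectionResult:
    """Ranked selected features with full diagnostics."""

    selected: tuple[str, ...]
    mi_values: tuple[float, ...]
    cluster_of: dict[str, int]
    relevance_score_of: dict[str, float]
    report: RelevanceReport
    params: SVFSParams

    def to_rows(self) -> list[dict]:
        return [
            {
                "rank": r + 1,
                "feature_id": f,
                "cluster": self.cluster_of[f],
                "mi": mi,
                "relevance_score": self.relevance_score_of[f],
            }
            for r, (f, mi) in enumerate(zip(self.selected, self.mi_values))
        ]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "selected": list(self.selected),
            "mi_values": list(self.mi_values),
            "cluster_of": dict(self.cluster_of),
            "relevance_score_of": dict(self.relevance_score_of),
            "report": self.report.to_dict(),
            "params": {
                k: v for k, v in asdict(self.params).items()
            },
        }


def entropy(labels: Sequence) -> float:
    """Plug-in Shannon entropy of a discrete sample, in bits."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise InputError("entropy of an empty vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _n_bins(m: int, mi_bins: Union[int, str]) -> int:
    if mi_bins == "sturges":
        return int(math.ceil(math.log2(m))) + 1 if m > 1 else 1
    return int(mi_bins)


def discretize(feature: np.ndarray, mi_bins: Union[int, str] = "sturges") -> np.ndarray:
    """Equal-width binning of a real vector; constant vectors map to bin 0."""
    feature = np.asarray(feature, dtype=float).ravel()
    lo, hi = float(feature.min()), float(feature.max())
    if hi == lo:
        return np.zeros(feature.size, dtype=int)
    nb = _n_bins(feature.size, mi_bins)
    edges = np.linspace(lo, hi, nb + 1)[1:-1]
    return np.searchsorted(edges, feature, side="right")


def mutual_information(
    feature: np.ndarray,
    labels: Sequence,
    mi_bins: Union[int, str] = "sturges",
) -> float:
    """Plug-in mutual information (bits) between a binned real feature and a
    discrete label vector; clamped at 0.  A constant feature carries 0 bits."""
    feature = np.asarray(feature, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if feature.size != labels.size:
        raise InputError(
            f"feature length {feature.size} != label length {labels.size}"
        )
    if feature.size < 2:
        raise InputError("mutual information needs at least 2 samples")
    x = discretize(feature, mi_bins)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(labels, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def rank_candidates(
    subcluster: Sequence[str],
    relevance_scores: Mapping[str, float],
    beta: int = 5,
) -> list[str]:
    """Top-``beta`` members by descending relevance score (ties by original
    column order, i.e. the order given in ``relevance_scores``)."""
    if beta < 1:
        raise InputError(f"beta must be >= 1, got {beta}")
    order = {f: i for i, f in enumerate(relevance_scores)}
    missing = [f for f in subcluster if f not in order]
    if missing:
        raise InputError(f"no relevance score for features {missing}")
    ranked = sorted(subcluster, key=lambda f: (-relevance_scores[f], order[f]))
    return ranked[: min(beta, len(ranked))]


def _discrete_labels(b: np.ndarray, mi_bins: Union[int, str]) -> np.ndarray:
    """Class codes for MI: integer-valued labels pass through; continuous
    label vectors get the same equal-width binning as features."""
    if np.allclose(b, np.round(b)) and np.unique(b).size <= max(
        2, int(math.sqrt(b.size))
    ):
        return b.astype(int)
    return discretize(b, mi_bins)


def select_representatives(
    partition: ClusterPartition,
    D: LabeledDataset,
    relevance_scores: Mapping[str, float],
    params: SVFSParams,
    report: Optional[RelevanceReport] = None,
) -> SelectionResult:
    """One representative per (sub-)cluster: the max-MI member among its
    top-``beta`` relevance candidates; final list is MI-descending, truncated
    to ``k``.  Ties break toward the lower original column index."""
    if len(partition) == 0:
        raise InputError("empty partition")
    ids = D.A.feature_ids
    labels = _discrete_labels(D.b, params.mi_bins)
    col = {f: j for j, f in enumerate(ids)}
    reps: list[tuple[str, float, int]] = []  # (feature, mi, cluster index)
    for ci, cluster in enumerate(partition.clusters):
        members = [ids[i] for i in cluster]
        candidates = rank_candidates(members, relevance_scores, params.beta)
        best, best_mi = None, -1.0
        for f in candidates:
            mi = mutual_information(D.A.values[:, col[f]], labels, params.mi_bins)
            if mi > best_mi or (mi == best_mi and col[f] < col[best]):
                best, best_mi = f, mi
        reps.append((best, best_mi, ci))
    reps.sort(key=lambda t: (-t[1], col[t[0]]))
    reps = reps[: params.k]
    if report is None:
        report = _trivial_report(D, relevance_scores)
    return SelectionResult(
        selected=tuple(f for f, _, _ in reps),
        mi_values=tuple(mi for _, mi, _ in reps),
        cluster_of={ids[i]: ci for ci, c in enumerate(partition.clusters) for i in c},
        relevance_score_of={f: float(relevance_scores[f]) for f in ids},
        report=report,
        params=params,
    )


def _trivial_report(
    D: LabeledDataset, relevance_scores: Mapping[str, float]
) -> RelevanceReport:
    from .linalg import WeightVector

    ids = D.A.feature_ids
    return RelevanceReport(
        weights=WeightVector(x=np.zeros(len(ids)), feature_ids=ids),
        relevance_scores=np.array([relevance_scores[f] for f in ids]),
        kept_step1=ids,
        kept_step2=ids,
        tau1=0.0,
        tau2=0.0,
    )
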