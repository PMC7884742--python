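"""End-to-end selection pipeline and the cross-validation harness.

Stages, in order: least-squares weight filter -> signature-row filter ->
signature matrix of the reduced feature block -> thresholded feature graph ->
BFS clusters -> alpha-splitting -> per-cluster representative by mutual
information.  Per-stage sizes and thresholds are logged so the effect of the
two filtering steps is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from .clustering import (
    ClusterPartition,
    connected_components,
    split_clusters,
    threshold_signature,
)
from .exceptions import SVFSError
from .linalg import SignatureMatrix, signature_matrix
from .relevance import (
    LabeledDataset,
    RelevanceReport,
    reduce_dataset,
    signature_row_filter,
    weight_filter,
)
from .selection import SVFSParams, SelectionResult, select_representatives

__all__ = ["run_svfs", "PipelineArtifacts", "run_svfs_with_artifacts", "evaluate_cv"]

log = logging.getLogger("svfs")


@dataclass(frozen=True)
class PipelineArtifacts:
    """Intermediate products of one pipeline run, for export/inspection."""

    result: SelectionResult
    reduced: LabeledDataset
    signature: SignatureMatrix
    adjacency: sp.csr_matrix
    partition: ClusterPartition


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except SVFSError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_svfs_with_artifacts(
    D: LabeledDataset, params: Optional[SVFSParams] = None
) -> PipelineArtifacts:
    """As :func:`run_svfs` but also returning the intermediate artifacts."""
    params = params or SVFSParams()
    log.info("input: %d samples x %d features", D.n_samples, D.n_features)

    kept1, weights, tau1 = _stage("weight_filter", weight_filter, D, params.th_irr)
    log.info("weight filter: kept %d/%d (tau1=%.4g)", len(kept1), D.n_features, tau1)
    D1 = _stage("reduce_dataset", reduce_dataset, D, kept1)

    kept2, scores1, tau2 = _stage(
        "signature_row_filter", signature_row_filter, D1, params.th_irr
    )
    log.info("signature-row filter: kept %d/%d (tau2=%.4g)", len(kept2), len(kept1), tau2)
    D2 = _stage("reduce_dataset", reduce_dataset, D1, kept2)

    score_of = dict(zip(D1.A.feature_ids, scores1))
    report = RelevanceReport(
        weights=weights,
        relevance_scores=scores1,
        kept_step1=tuple(kept1),
        kept_step2=tuple(kept2),
        tau1=tau1,
        tau2=tau2,
    )

    S2 = _stage("signature_matrix", signature_matrix, D2.A, params.sv_tolerance)
    adjacency = _stage("threshold_signature", threshold_signature, S2, params.th_red)
    partition = _stage(
        "connected_components", connected_components, adjacency, D2.n_features
    )
    log.info(
        "graph: %d edges, %d clusters (%d multi-member)",
        adjacency.nnz // 2,
        len(partition),
        len(partition.multi_member()),
    )
    member_scores = np.array([score_of[f] for f in D2.A.feature_ids])
    partition = _stage("split_clusters", split_clusters, partition, member_scores, params.alpha)

    result = _stage(
        "select_representatives",
        select_representatives,
        partition,
        D2,
        score_of,
        params,
        report,
    )
    log.info("selected %d features", len(result.selected))
    return PipelineArtifacts(
        result=result, reduced=D2, signature=S2, adjacency=adjacency, partition=partition
    )


def run_svfs(D: LabeledDataset, params: Optional[SVFSParams] = None) -> SelectionResult:
    """Run the full selection pipeline on a labeled dataset.

    Deterministic given (data, params): no stage draws random numbers.
    """
    return run_svfs_with_artifacts(D, params).result


def evaluate_cv(
    D: LabeledDataset,
    params: Optional[SVFSParams] = None,
    folds: int = 5,
    repeats: int = 2,
    stratified: bool = True,
    classifier=None,
    seed: int = 0,
    selector: Callable[[LabeledDataset, SVFSParams], SelectionResult] = run_svfs,
):
    """Repeated (stratified) k-fold accuracy of a classifier on selected
    feature prefixes.

    Selection runs on the training folds only; the held-out fold is scored
    for every prefix length ``t`` of the selected list.  The classifier is
    any object honoring the sklearn fit/predict contract (default: random
    forest with library defaults); it is plumbing, not part of the method.

    Returns a pandas DataFrame with columns ``t`` and ``mean_accuracy``.
    """
    import pandas as pd
    from sklearn.base import clone
    from sklearn.model_selection import KFold, StratifiedKFold

    from .exceptions import InputError

    params = params or SVFSParams()
    if folds < 2:
        raise InputError(f"folds must be >= 2, got {folds}")
    if classifier is None:
        from sklearn.ensemble import RandomForestClassifier

        classifier = RandomForestClassifier(random_state=seed)
    y = D.b
    classes, counts = np.unique(y, return_counts=True)
    if stratified and counts.min() < folds:
        raise InputError(
            f"class {classes[int(np.argmin(counts))]!r} has {counts.min()} "
            f"members, fewer than folds={folds}"
        )
    col = {f: j for j, f in enumerate(D.A.feature_ids)}
    acc: dict[int, list[float]] = {}
    for rep in range(repeats):
        if stratified:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train, test in splitter.split(D.A.values, y):
            D_train = LabeledDataset(
                A=type(D.A)(values=D.A.values[train], feature_ids=D.A.feature_ids),
                b=y[train],
                label_name=D.label_name,
            )
            selected = selector(D_train, params).selected
            for t in range(1, len(selected) + 1):
                idx = [col[f] for f in selected[:t]]
                clf = clone(classifier)
                clf.fit(D.A.values[np.ix_(train, idx)], y[train])
                pred = clf.predict(D.A.values[np.ix_(test, idx)])
                acc.setdefault(t, []).append(float(np.mean(pred == y[test])))
    rows = [{"t": t, "mean_accuracy": float(np.mean(v))} for t, v in sorted(acc.items())]
    return pd.DataFrame(rows)
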