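"""Two-step removal of features irrelevant to the class label.

Step 1 screens by the minimum-norm least-squares weights of ``A x = b``:
``|x_i|`` measures how much feature ``i`` contributes to explaining the
label, and features below a mean-scaled soft threshold are dropped.

Step 2 screens by the last row of the signature matrix of ``D = [A | b]``:
``|S_D[i, n+1]|`` is nonzero exactly when feature ``i`` sits in the same
linear-dependency cluster as the label, so its magnitude acts as a relevance
score.  Scores below ``mean * Th_irr`` are zeroed as noise and only features
at or above the cutoff ``mean * (Th_irr + 1)`` survive.  Both thresholds are
scaled by the mean magnitude so that one dimensionless ``Th_irr`` (default 3)
works across datasets of very different scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import EmptyResultError, InputError
from .linalg import FeatureMatrix, WeightVector, minnorm_weights, signature_matrix

__all__ = [
    "LabeledDataset",
    "RelevanceReport",
    "weight_filter",
    "signature_row_filter",
    "reduce_dataset",
]


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix plus its label column: ``D = [A | b]``.

    ``b`` may hold integer class codes (classification) or real values (a
    planted linear combination); it always enters the signature matrix of
    ``D`` as a numeric column.
    """

    A: FeatureMatrix
    b: np.ndarray
    label_name: str = "label"

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float).ravel()
        if b.shape[0] != self.A.n_samples:
            raise InputError(
                f"label length {b.shape[0]} != {self.A.n_samples} samples"
            )
        if not np.all(np.isfinite(b)):
            i = int(np.argwhere(~np.isfinite(b))[0])
            raise InputError(f"non-finite label at sample row {i}")
        if self.label_name in self.A.feature_ids:
            raise InputError(
                f"label name {self.label_name!r} collides with a feature id"
            )
        object.__setattr__(self, "b", b)

    @property
    def n_samples(self) -> int:
        return self.A.n_samples

    @property
    def n_features(self) -> int:
        return self.A.n_features

    def joint_matrix(self) -> FeatureMatrix:
        """``[A | b]`` as one feature matrix with the label as last column."""
        values = np.column_stack([self.A.values, self.b])
        return FeatureMatrix(
            values=values, feature_ids=self.A.feature_ids + (self.label_name,)
        )


@dataclass(frozen=True)
class RelevanceReport:
    """Diagnostics of the two filtering steps."""

    weights: WeightVector
    relevance_scores: np.ndarray  # |last row of S_D| per surviving-step-1 feature
    kept_step1: tuple[str, ...]
    kept_step2: tuple[str, ...]
    tau1: float
    tau2: float

    def to_dict(self) -> dict:
        return {
            "tau1": self.tau1,
            "tau2": self.tau2,
            "kept_step1": list(self.kept_step1),
            "kept_step2": list(self.kept_step2),
            "n_kept_step1": len(self.kept_step1),
            "n_kept_step2": len(self.kept_step2),
        }


def weight_filter(
    D: LabeledDataset, th_irr: float = 3.0
) -> tuple[list[str], WeightVector, float]:
    """Keep features whose least-squares weight magnitude reaches the
    mean-scaled cutoff ``tau1 = mean(|x|) * th_irr``.

    Returns ``(kept feature ids in column order, weights, tau1)``.
    """
    if th_irr < 0:
        raise InputError(f"th_irr must be >= 0, got {th_irr}")
    w = minnorm_weights(D.A, D.b)
    absx = np.abs(w.x)
    if not np.any(absx > 1e-12 * max(1.0, float(np.abs(D.b).max()))):
        raise EmptyResultError(
            "all least-squares weights are zero: the label is orthogonal to "
            "the column space — no relevant features"
        )
    tau1 = float(absx.mean() * th_irr)
    kept = [f for f, xi in zip(D.A.feature_ids, absx) if xi >= tau1]
    if not kept:
        raise EmptyResultError(
            f"no feature weight reaches tau1={tau1:.4g}; no relevant features"
        )
    return kept, w, tau1


def signature_row_filter(
    D_reduced: LabeledDataset, th_irr: float = 3.0
) -> tuple[list[str], np.ndarray, float]:
    """Keep features coupled to the label in the signature matrix of
    ``[A | b]``.

    The score of feature ``i`` is ``|S_D[i, last]|``.  Scores below
    ``mean * th_irr`` are zeroed; the survivors are the descending-sorted
    prefix with score >= ``tau2 = mean * (th_irr + 1)``.  Returns
    ``(kept ids in column order, zeroed scores for all features, tau2)``.
    """
    if th_irr < 0:
        raise InputError(f"th_irr must be >= 0, got {th_irr}")
    S_D = signature_matrix(D_reduced.joint_matrix())
    scores = np.abs(S_D.last_row()[:-1])  # drop the (b, b) entry
    if not np.any(scores > 1e-12):
        raise EmptyResultError(
            "label is in a singleton cluster of S_D — no feature correlates "
            "with b"
        )
    mean_s = float(scores.mean())
    scores = np.where(scores < mean_s * th_irr, 0.0, scores)
    tau2 = mean_s * (th_irr + 1.0)
    kept = [f for f, s in zip(D_reduced.A.feature_ids, scores) if s >= tau2]
    if not kept:
        raise EmptyResultError(
            f"no relevance score reaches tau2={tau2:.4g}; no relevant features"
        )
    return kept, scores, tau2


def reduce_dataset(D: LabeledDataset, kept: Sequence[str]) -> LabeledDataset:
    """Restrict ``D`` to the kept feature columns (order preserved)."""
    kept = list(kept)
    if not kept:
        raise InputError("kept feature list is empty")
    missing = [f for f in kept if f not in D.A.feature_ids]
    if missing:
        raise InputError(f"unknown feature ids: {missing}")
    keep_set = set(kept)
    idx = [j for j, f in enumerate(D.A.feature_ids) if f in keep_set]
    A = FeatureMatrix(
        values=D.A.values[:, idx],
        feature_ids=[D.A.feature_ids[j] for j in idx],
    )
    return LabeledDataset(A=A, b=D.b, label_name=D.label_name)
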