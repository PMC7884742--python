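"""Rank, minimum-norm least squares, and the null-space signature matrix.

The central object is the *signature matrix* ``S = I - pinv(A) @ A`` of an
``m x n`` data matrix ``A`` (samples in rows, features in columns).  ``S``
equals the orthogonal projector ``P`` onto the null space of ``A``, so its
off-diagonal support encodes exact linear dependencies between columns:
features in different dependency clusters always pair to a zero entry, while
features inside one cluster are connected through nonzero entries.

Everything here is built on a single SVD per matrix.  The rank cutoff is the
standard numerical-rank convention ``max(m, n) * eps * sigma_max`` and is
shared by :func:`numerical_rank`, :func:`signature_matrix` and
:func:`minnorm_weights` so that all downstream block-structure results agree
on what "zero singular value" means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InputError, NumericalError

__all__ = [
    "FeatureMatrix",
    "SignatureMatrix",
    "WeightVector",
    "numerical_rank",
    "signature_matrix",
    "minnorm_weights",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """An ``m x n`` real matrix with named feature columns.

    Rows are samples, columns are features.  Feature identifiers are unique
    and ordered to match the columns.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InputError(f"feature matrix must be 2-D, got shape {values.shape}")
        m, n = values.shape
        if m < 1 or n < 1:
            raise InputError(f"feature matrix must be at least 1x1, got {m}x{n}")
        ids = self.feature_ids
        if ids is None:
            ids = tuple(f"F{j + 1}" for j in range(n))
        else:
            ids = tuple(str(f) for f in ids)
        if len(ids) != n:
            raise InputError(
                f"{len(ids)} feature ids for {n} columns"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({f for f in ids if list(ids).count(f) > 1})
            raise InputError(f"duplicate feature ids: {dupes}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


@dataclass(frozen=True)
class SignatureMatrix:
    """Orthogonal projector onto the null space of a feature matrix.

    ``S`` is symmetric, idempotent, and has ``trace(S) = n - rank``.  Entries
    are kept at full precision; any rounding is a display/test concern.
    """

    S: np.ndarray
    rank: int
    sv_tolerance: float

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def last_row(self) -> np.ndarray:
        return self.S[-1]


@dataclass(frozen=True)
class WeightVector:
    """Minimum-norm least-squares weights, aligned with feature columns."""

    x: np.ndarray
    feature_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.x)


def _check_finite(values: np.ndarray, feature_ids: Sequence[str]) -> None:
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise InputError(
            f"non-finite value {values[i, j]!r} at sample row {i}, "
            f"feature {feature_ids[j]!r}"
        )


def _svd(M: FeatureMatrix, sv_tolerance: Optional[float]):
    """Thin SVD plus the resolved singular-value cutoff and numerical rank."""
    A = M.values
    _check_finite(A, M.feature_ids)
    try:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - hardware dependent
        raise NumericalError(
            f"SVD did not converge on a {A.shape[0]}x{A.shape[1]} matrix"
        ) from exc
    if sv_tolerance is None:
        sigma_max = s[0] if s.size else 0.0
        sv_tolerance = max(A.shape) * np.finfo(A.dtype).eps * sigma_max
    elif sv_tolerance < 0:
        raise InputError(f"sv_tolerance must be >= 0, got {sv_tolerance}")
    rank = int(np.count_nonzero(s > sv_tolerance))
    return U, s, Vt, float(sv_tolerance), rank


def numerical_rank(M: FeatureMatrix, sv_tolerance: Optional[float] = None) -> int:
    """Number of singular values strictly above the cutoff.

    The default cutoff is ``max(m, n) * eps * sigma_max``.
    """
    *_, rank = _svd(M, sv_tolerance)
    return rank


def signature_matrix(
    M: FeatureMatrix, sv_tolerance: Optional[float] = None
) -> SignatureMatrix:
    """Projector onto the null space of ``M``, computed as ``Vbar @ Vbar.T``.

    ``Vbar`` collects the right singular vectors whose singular value falls
    at or below the cutoff (including the ``n - min(m, n)`` directions a wide
    matrix omits from its thin SVD).  This is numerically equivalent to
    ``I - pinv(M) @ M`` but never forms the pseudo-inverse.
    """
    _, _, Vt, tol, rank = _svd(M, sv_tolerance)
    n = M.n_features
    Vbar_t = Vt[rank:]  # null directions present in the thin SVD
    S = Vbar_t.T @ Vbar_t
    if Vt.shape[0] < n:
        # wide matrix: the thin SVD spans only min(m, n) right directions;
        # the remaining n - min(m, n) null directions complete I - V V^T.
        S = S + (np.eye(n) - Vt.T @ Vt)
    S = (S + S.T) / 2.0
    return SignatureMatrix(S=S, rank=rank, sv_tolerance=tol)


def minnorm_weights(
    M: FeatureMatrix,
    b: np.ndarray,
    sv_tolerance: Optional[float] = None,
) -> WeightVector:
    """Minimum-norm least-squares solution ``x = pinv(M) @ b``.

    Uses the same singular-value cutoff as :func:`numerical_rank`, so the
    solution is orthogonal to the numerical null space of ``M``.
    """
    b = np.asarray(b, dtype=float).ravel()
    if b.shape[0] != M.n_samples:
        raise InputError(
            f"label vector length {b.shape[0]} does not match "
            f"{M.n_samples} samples"
        )
    if not np.all(np.isfinite(b)):
        i = int(np.argwhere(~np.isfinite(b))[0])
        raise InputError(f"non-finite label value at sample row {i}")
    U, s, Vt, _, rank = _svd(M, sv_tolerance)
    with np.errstate(divide="ignore"):
        inv_s = np.zeros_like(s)
        inv_s[:rank] = 1.0 / s[:rank]
    x = Vt.T @ (inv_s * (U.T @ b))
    return WeightVector(x=x, feature_ids=M.feature_ids)
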