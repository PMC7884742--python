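"""Synthetic matrices with planted exact linear dependencies.

A *planted* matrix is generated so that a chosen set of exact linear
relations ``sum_j c_j F_j = 0`` are the only dependencies among its columns;
all remaining degrees of freedom are generic (i.i.d. standard normal).  Its
null space is then exactly the span of the relation vectors, which makes the
signature matrix analytically known and provides an implementation-
independent oracle (:func:`projection_oracle`) for the SVD route.

A label vector can be planted as a stated linear combination of columns,
optionally discretized into balanced classes by equal-frequency binning.

The module also ships a small reference configuration
(:func:`reference_relations`, :func:`reference_label_combo`): a 100 x 80
matrix with two planted dependency clusters, {F1..F4} (two relations) and
{F5..F11} (five relations), and a label driven by F1, F3, F9 and F14.  It is
used throughout the documentation and tests because every quantity of
interest (rank 73, projector entries, minimum-norm weights) is exactly
determined by the seven relation vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import ConstructionError, InputError
from .linalg import FeatureMatrix, SignatureMatrix
from .relevance import LabeledDataset

__all__ = [
    "RelationSet",
    "PlantedDatasetSpec",
    "generate_planted_matrix",
    "plant_label",
    "projection_oracle",
    "minimal_relations",
    "reference_relations",
    "reference_label_combo",
    "write_dataset",
    "read_spec_yaml",
]

Relation = Mapping[int, float]


@dataclass(frozen=True)
class RelationSet:
    """Linearly independent exact dependence relations among named columns.

    Each relation maps 1-based feature indices to coefficients and denotes
    ``sum_j coeff_j * F_j = 0``.
    """

    relations: tuple[dict[int, float], ...]
    n_features: int

    def __init__(self, relations: Sequence[Relation], n_features: int) -> None:
        rels = tuple({int(k): float(v) for k, v in r.items()} for r in relations)
        if n_features < 1:
            raise InputError(f"n_features must be >= 1, got {n_features}")
        for i, r in enumerate(rels):
            if len([c for c in r.values() if c != 0.0]) < 2:
                raise InputError(
                    f"relation {i} needs at least 2 nonzero coefficients: {r}"
                )
            for j in r:
                if not 1 <= j <= n_features:
                    raise InputError(
                        f"relation {i} references feature index {j} "
                        f"outside [1, {n_features}]"
                    )
        object.__setattr__(self, "relations", rels)
        object.__setattr__(self, "n_features", n_features)
        if rels:
            R = self.as_matrix()
            if np.linalg.matrix_rank(R) < len(rels):
                raise InputError("relation vectors are linearly dependent")

    def __len__(self) -> int:
        return len(self.relations)

    def as_matrix(self) -> np.ndarray:
        """Stack the relations as rows of a ``k x n_features`` matrix."""
        R = np.zeros((len(self.relations), self.n_features))
        for i, r in enumerate(self.relations):
            for j, c in r.items():
                R[i, j - 1] = c
        return R

    def groups(self) -> list[set[int]]:
        """Connected groups of features coupled through shared relations."""
        parent = {}

        def find(a):
            while parent.get(a, a) != a:
                parent[a] = parent.get(parent[a], parent[a])
                a = parent[a]
            return a

        for r in self.relations:
            idx = [j for j, c in r.items() if c != 0.0]
            for j in idx[1:]:
                ra, rb = find(idx[0]), find(j)
                if ra != rb:
                    parent[rb] = ra
        out: dict[int, set[int]] = {}
        for r in self.relations:
            for j, c in r.items():
                if c != 0.0:
                    out.setdefault(find(j), set()).add(j)
        return sorted(out.values(), key=min)


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Recipe for a planted matrix and (optionally) a planted label.

    ``label_combo`` maps 1-based feature indices to the coefficients of the
    linear combination defining ``b``; ``n_classes`` discretizes ``b`` into
    equal-frequency classes.  ``noise_sd`` perturbs only the dependent
    (pivot) columns, degrading the exact relations.
    """

    m: int
    n: int
    relations: RelationSet
    label_combo: Optional[dict[int, float]] = None
    n_classes: Optional[int] = None
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise InputError(f"need m, n >= 1, got m={self.m}, n={self.n}")
        if self.relations.n_features != self.n:
            raise InputError(
                f"relations are over {self.relations.n_features} features "
                f"but spec has n={self.n}"
            )
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.label_combo is not None:
            for j in self.label_combo:
                if not 1 <= j <= self.n:
                    raise InputError(f"label_combo index {j} outside [1, {self.n}]")
        if self.n_classes is not None and self.n_classes < 2:
            raise InputError(f"n_classes must be >= 2, got {self.n_classes}")

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "n": self.n,
            "relations": [
                {str(j): c for j, c in r.items()} for r in self.relations.relations
            ],
            "label_combo": (
                {str(j): c for j, c in self.label_combo.items()}
                if self.label_combo
                else None
            ),
            "n_classes": self.n_classes,
            "seed": self.seed,
            "noise_sd": self.noise_sd,
        }


def _assign_pivots(relations: RelationSet) -> list[int]:
    """One pivot feature per relation: lowest unassigned index with a nonzero
    coefficient, scanning relations in their given order."""
    pivots: list[int] = []
    for i, r in enumerate(relations.relations):
        candidates = sorted(j for j, c in r.items() if c != 0.0 and j not in pivots)
        if not candidates:
            raise ConstructionError(
                f"relation {i} ({r}) has no feature left to serve as pivot; "
                f"already assigned pivots: {sorted(pivots)}"
            )
        pivots.append(candidates[0])
    return pivots


def generate_planted_matrix(spec: PlantedDatasetSpec) -> FeatureMatrix:
    """Materialize a matrix whose only column dependencies are the relations.

    Free columns are i.i.d. standard normal from the seeded generator.  Pivot
    columns (one per relation) are solved jointly from the relation system,
    so mutually referencing relations are fine; an error is raised only when
    a valid pivot assignment does not exist.  With ``noise_sd = 0`` every
    relation holds exactly.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n
    R = spec.relations.as_matrix()
    if len(spec.relations) == 0:
        return FeatureMatrix(values=rng.standard_normal((m, n)))
    pivots = _assign_pivots(spec.relations)
    piv0 = [p - 1 for p in pivots]
    free0 = [j for j in range(n) if j not in piv0]
    R_piv = R[:, piv0]
    if abs(np.linalg.det(R_piv)) < 1e-12 * max(1.0, np.abs(R_piv).max()) ** len(piv0):
        raise ConstructionError(
            f"pivot submatrix for pivots {pivots} is singular; the relations "
            "cannot be solved with this pivot assignment"
        )
    A = np.empty((m, n))
    A[:, free0] = rng.standard_normal((m, len(free0)))
    # R_piv @ A_piv^T + R_free @ A_free^T = 0  =>  solve for the pivot block
    A[:, piv0] = -np.linalg.solve(R_piv, R[:, free0] @ A[:, free0].T).T
    if spec.noise_sd > 0:
        A[:, piv0] += spec.noise_sd * rng.standard_normal((m, len(piv0)))
    return FeatureMatrix(values=A)


def plant_label(A: FeatureMatrix, spec: PlantedDatasetSpec) -> LabeledDataset:
    """Attach the planted label ``b = sum_j c_j F_j`` to a generated matrix.

    With ``n_classes`` set, ``b`` is replaced by its equal-frequency quantile
    bin index in ``0..n_classes-1`` (class sizes differ by at most one for
    ties-free continuous ``b``).
    """
    if spec.label_combo is None:
        raise InputError("spec has no label_combo; nothing to plant")
    b = np.zeros(A.n_samples)
    for j, c in spec.label_combo.items():
        b += c * A.values[:, j - 1]
    if spec.n_classes is not None:
        edges = np.quantile(b, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
        b = np.searchsorted(edges, b, side="right").astype(float)
    return LabeledDataset(A=A, b=b, label_name="b")


def projection_oracle(relations: RelationSet) -> SignatureMatrix:
    """Orthogonal projector onto the span of the relation vectors, via QR.

    For a noiseless planted matrix the null space *is* that span, so this is
    an SVD-free oracle for :func:`svfs.linalg.signature_matrix`.
    """
    n = relations.n_features
    if len(relations) == 0:
        return SignatureMatrix(S=np.zeros((n, n)), rank=n, sv_tolerance=0.0)
    R = relations.as_matrix()
    Q, Rfac = np.linalg.qr(R.T)  # columns of Q: orthonormal basis of the span
    if np.abs(np.diag(Rfac)).min() < 1e-10 * np.abs(R).max():
        raise InputError("relation vectors are (numerically) dependent")
    P = Q @ Q.T
    return SignatureMatrix(S=(P + P.T) / 2.0, rank=n - len(relations), sv_tolerance=0.0)


def minimal_relations(relations: RelationSet, cluster: set[int]) -> RelationSet:
    """Canonical minimal relations of one dependency cluster.

    Restricts the relation vectors to the cluster's coordinates and reduces
    them (Gauss-Jordan) to the unique form in which each relation carries
    coefficient -1 on a distinct pivot feature — the lowest cluster indices —
    and 0 on every other pivot.  For the reference cluster {F1..F4} this
    yields ``-F1 - 0.5 F3 + 7.5 F4 = 0`` and ``-F2 - (1/6) F3 + 0.5 F4 = 0``.
    """
    cluster = set(int(j) for j in cluster)
    cols = sorted(cluster)
    touching = []
    for i, r in enumerate(relations.relations):
        support = {j for j, c in r.items() if c != 0.0}
        if support & cluster:
            if not support <= cluster:
                raise InputError(
                    f"cluster {sorted(cluster)} is not closed under relation "
                    f"{i}: it also touches {sorted(support - cluster)}"
                )
            touching.append(r)
    if not touching:
        return RelationSet(relations=[], n_features=relations.n_features)
    V = np.zeros((len(touching), len(cols)))
    pos = {j: k for k, j in enumerate(cols)}
    for i, r in enumerate(touching):
        for j, c in r.items():
            V[i, pos[j]] = c
    V = _rref(V)
    out = []
    for row in V:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size == 0:
            continue
        rel = {cols[k]: -row[k] for k in nz}  # pivot coefficient becomes -1
        out.append(rel)
    return RelationSet(relations=out, n_features=relations.n_features)


def _rref(M: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Reduced row echelon form with partial pivoting."""
    M = M.astype(float).copy()
    lead = 0
    rows, cols = M.shape
    for r in range(rows):
        if lead >= cols:
            break
        piv = r + int(np.argmax(np.abs(M[r:, lead])))
        while abs(M[piv, lead]) <= tol:
            lead += 1
            if lead >= cols:
                return M
            piv = r + int(np.argmax(np.abs(M[r:, lead])))
        M[[r, piv]] = M[[piv, r]]
        M[r] /= M[r, lead]
        others = [i for i in range(rows) if i != r]
        M[others] -= np.outer(M[others, lead], M[r])
        lead += 1
    return M


def reference_relations(n_features: int = 80) -> RelationSet:
    """The worked-example relation set: two planted clusters in 80 columns.

    Cluster {F1..F4} satisfies two relations and cluster {F5..F11} five, so a
    generic 100 x 80 realization has rank 73.  Within the second cluster the
    free directions are F10 and F11 (F5 = F10 + 3 F11, F6 = 4 F10 + 2 F11,
    F7 = -F10 - 3 F11, F8 = 3 F10 + 2 F11, F9 = 6 F10 + 18 F11).
    """
    rels = [
        {1: -1, 2: 3, 4: 6},
        {6: -1, 5: 2, 10: 2, 11: -4},
        {3: -1, 2: -6, 4: 3},
        {7: -1, 10: -1, 11: -3},
        {5: -1, 11: 3, 10: 1},
        {8: -1, 10: 3, 11: 2},
        {9: -1, 5: 5, 7: -1},
    ]
    return RelationSet(relations=rels, n_features=n_features)


def reference_label_combo() -> dict[int, float]:
    """Label of the worked example: ``b = F1 - 3 F3 + 4 F9 - F14``.

    It straddles both planted clusters (F1, F3 in the first, F9 in the
    second) plus the singleton F14, so the relevance filter should retain
    exactly those clusters.
    """
    return {1: 1.0, 3: -3.0, 9: 4.0, 14: -1.0}


def write_dataset(dataset: LabeledDataset, spec: PlantedDatasetSpec, out_dir) -> Path:
    """Emit the dataset as CSV (samples x features, label last) plus a
    side-car JSON of the generating spec for provenance.  Returns the CSV
    path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(dataset.A.values, columns=list(dataset.A.feature_ids))
    df[dataset.label_name] = dataset.b
    csv_path = out_dir / "dataset.csv"
    df.to_csv(csv_path, index=False)
    (out_dir / "dataset.spec.json").write_text(
        json.dumps(spec.to_dict(), indent=2) + "\n"
    )
    return csv_path


def read_spec_yaml(path) -> PlantedDatasetSpec:
    """Load a :class:`PlantedDatasetSpec` from a YAML file.

    Expected keys mirror the dataclass fields; relation and label-combo
    coefficient maps are keyed by 1-based feature index.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        relations = RelationSet(
            relations=[{int(k): float(v) for k, v in r.items()} for r in raw.get("relations", [])],
            n_features=int(raw["n"]),
        )
        combo = raw.get("label_combo")
        if combo is not None:
            combo = {int(k): float(v) for k, v in combo.items()}
        return PlantedDatasetSpec(
            m=int(raw["m"]),
            n=int(raw["n"]),
            relations=relations,
            label_combo=combo,
            n_classes=raw.get("n_classes"),
            seed=int(raw.get("seed", 0)),
            noise_sd=float(raw.get("noise_sd", 0.0)),
        )
    except KeyError as exc:
        raise InputError(f"simulation spec is missing required key {exc}") from exc
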