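"""Feature selection for high-dimensional tabular data via the null-space
signature matrix S = I - pinv(A) @ A.

The signature matrix is the orthogonal projector onto the null space of the
data matrix: its off-diagonal support reveals which feature columns are
linearly dependent.  The pipeline removes features uncorrelated with the
class label (two mean-scaled soft-threshold steps), clusters the rest by
connected components of the thresholded signature matrix, and keeps one
representative per cluster — the member sharing the most information (plug-in
mutual information, bits) with the label.
"""

from .exceptions import (
    ConstructionError,
    EmptyResultError,
    InputError,
    NumericalError,
    SVFSError,
)
from .linalg import (
    FeatureMatrix,
    SignatureMatrix,
    WeightVector,
    minnorm_weights,
    numerical_rank,
    signature_matrix,
)
from .relevance import (
    LabeledDataset,
    RelevanceReport,
    reduce_dataset,
    signature_row_filter,
    weight_filter,
)
from .clustering import (
    ClusterPartition,
    connected_components,
    split_clusters,
    threshold_signature,
)
from .selection import (
    SVFSParams,
    SelectionResult,
    entropy,
    mutual_information,
    rank_candidates,
    select_representatives,
)
from .synthetic import (
    PlantedDatasetSpec,
    RelationSet,
    generate_planted_matrix,
    minimal_relations,
    plant_label,
    projection_oracle,
    reference_label_combo,
    reference_relations,
)
from .pipeline import evaluate_cv, run_svfs, run_svfs_with_artifacts
from .io import RunConfig, read_dataset, write_selection

__version__ = "0.1.0"

__all__ = [
    "ConstructionError",
    "EmptyResultError",
    "InputError",
    "NumericalError",
    "SVFSError",
    "FeatureMatrix",
    "SignatureMatrix",
    "WeightVector",
    "minnorm_weights",
    "numerical_rank",
    "signature_matrix",
    "LabeledDataset",
    "RelevanceReport",
    "reduce_dataset",
    "signature_row_filter",
    "weight_filter",
    "ClusterPartition",
    "connected_components",
    "split_clusters",
    "threshold_signature",
    "SVFSParams",
    "SelectionResult",
    "entropy",
    "mutual_information",
    "rank_candidates",
    "select_representatives",
    "PlantedDatasetSpec",
    "RelationSet",
    "generate_planted_matrix",
    "minimal_relations",
    "plant_label",
    "projection_oracle",
    "reference_label_combo",
    "reference_relations",
    "evaluate_cv",
    "run_svfs",
    "run_svfs_with_artifacts",
    "RunConfig",
    "read_dataset",
    "write_selection",
]
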