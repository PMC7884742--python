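import numpy as np
import pytest

import svfs

# Printed 11x11 leading block of the reference signature matrix (2-decimal
# display); everything outside rows/cols 1..11 is exactly zero.
REFERENCE_BLOCK = np.array([
    [0.02, -0.07, 0.00, -0.13, 0, 0, 0, 0, 0, 0, 0],
    [-0.07, 0.98, 0.13, 0.00, 0, 0, 0, 0, 0, 0, 0],
    [0.00, 0.13, 0.02, -0.07, 0, 0, 0, 0, 0, 0, 0],
    [-0.13, 0.00, -0.07, 0.98, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0.97, 0.00, 0.03, 0.00, -0.16, 0.01, -0.01],
    [0, 0, 0, 0, 0.00, 0.37, 0.00, -0.44, 0.00, -0.19, 0.06],
    [0, 0, 0, 0, 0.03, 0.00, 0.97, 0.00, 0.16, -0.01, 0.01],
    [0, 0, 0, 0, 0.00, -0.44, 0.00, 0.69, -0.03, -0.13, 0.04],
    [0, 0, 0, 0, -0.16, 0.00, 0.16, -0.03, 0.06, 0.03, -0.06],
    [0, 0, 0, 0, 0.01, -0.19, -0.01, -0.13, 0.03, 0.94, 0.02],
    [0, 0, 0, 0, -0.01, 0.06, 0.01, 0.04, -0.06, 0.02, 0.99],
])

# Reference minimum-norm weights (2-decimal display), zero beyond F14.
REFERENCE_WEIGHTS_14 = [0.98, 0.46, -2.93, -0.07, 0.63, -0.02, -0.63, 0.11,
                        3.77, -0.13, 0.25, 0.00, 0.00, -1.00]

# Reference label-coupling row of S_[A|b] (4-decimal display) at F1..F14.
# The F14 entry is exactly 2185/58658 = 0.037250, a half-ulp boundary.
REFERENCE_LABEL_ROW_14 = [-0.0364, -0.0170, 0.1093, 0.0024, -0.0234, 0.0006,
                          0.0234, -0.0043, -0.1403, 0.0049, -0.0094, 0.0, 0.0,
                          0.0372]


@pytest.fixture(scope="session")
def reference_relations():
    return svfs.reference_relations()


@pytest.fixture(scope="session")
def reference_spec(reference_relations):
    return svfs.PlantedDatasetSpec(
        m=100, n=80, relations=reference_relations,
        label_combo=svfs.reference_label_combo(), seed=7,
    )


@pytest.fixture(scope="session")
def reference_matrix(reference_spec):
    return svfs.generate_planted_matrix(reference_spec)


@pytest.fixture(scope="session")
def reference_dataset(reference_spec, reference_matrix):
    return svfs.plant_label(reference_matrix, reference_spec)


@pytest.fixture(scope="session")
def reference_signature(reference_matrix):
    return svfs.signature_matrix(reference_matrix)


def random_relation_set(rng, n_features):
    """A random valid RelationSet on disjoint feature groups."""
    perm = rng.permutation(n_features) + 1
    pos = 0
    relations = []
    while pos + 3 <= n_features and len(relations) < 3:
        size = int(rng.integers(3, 5))
        if pos + size > n_features:
            break
        group = sorted(perm[pos:pos + size].tolist())
        n_rel = int(rng.integers(1, size - 1))
        for _ in range(n_rel):
            # continuous coefficients: degenerate conspiracies (singular pivot
            # blocks, hidden sub-clusters inside one support group) have
            # probability zero, so the support groups are true clusters
            coeffs = rng.uniform(0.5, 3.0, size=size) * rng.choice([-1, 1], size=size)
            relations.append({int(j): float(cc) for j, cc in zip(group, coeffs)})
        pos += size
    try:
        return svfs.RelationSet(relations=relations, n_features=n_features)
    except svfs.InputError:
        return svfs.RelationSet(relations=[], n_features=n_features)
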