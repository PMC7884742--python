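"""Planted-dependency generator and its analytic oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as cc_oracle
from hypothesis import given, settings, strategies as st

import svfs

from conftest import random_relation_set


class TestGeneratePlantedMatrix:
    def test_reference_rank(self, reference_matrix):
        assert svfs.numerical_rank(reference_matrix) == 73

    def test_no_relations_generic_full_rank(self):
        spec = svfs.PlantedDatasetSpec(
            m=12, n=8, relations=svfs.RelationSet([], n_features=8), seed=0
        )
        assert svfs.numerical_rank(svfs.generate_planted_matrix(spec)) == 8

    def test_single_relation_duplicates_column(self):
        rels = svfs.RelationSet([{1: 1.0, 2: -1.0}], n_features=5)
        spec = svfs.PlantedDatasetSpec(m=10, n=5, relations=rels, seed=1)
        A = svfs.generate_planted_matrix(spec)
        assert np.allclose(A.values[:, 0], A.values[:, 1])

    def test_mutually_referencing_pivots_are_solved(self):
        # F1 needs F2's pivot column and vice versa; a joint solve handles it
        rels = svfs.RelationSet(
            [{1: -1.0, 2: 2.0, 3: 1.0}, {2: -1.0, 1: 2.0, 4: 1.0}], n_features=4
        )
        spec = svfs.PlantedDatasetSpec(m=8, n=4, relations=rels, seed=2)
        A = svfs.generate_planted_matrix(spec).values
        assert np.allclose(-A[:, 0] + 2 * A[:, 1] + A[:, 2], 0, atol=1e-10)
        assert np.allclose(-A[:, 1] + 2 * A[:, 0] + A[:, 3], 0, atol=1e-10)

    def test_pivot_starved_relation_errors(self):
        rels = svfs.RelationSet(
            [{1: 1.0, 2: 1.0}, {2: 1.0, 3: 1.0}, {1: 1.0, 2: -1.0}], n_features=3
        )
        spec = svfs.PlantedDatasetSpec(m=6, n=3, relations=rels, seed=0)
        with pytest.raises(svfs.ConstructionError, match="pivot"):
            svfs.generate_planted_matrix(spec)

    def test_noise_degrades_relations(self, reference_relations):
        spec = svfs.PlantedDatasetSpec(
            m=100, n=80, relations=reference_relations, seed=7, noise_sd=0.1
        )
        A = svfs.generate_planted_matrix(spec)
        assert svfs.numerical_rank(A) == 80  # noise breaks exactness


class TestPlantLabel:
    def test_continuous_label_is_exact_combo(self, reference_matrix, reference_dataset):
        combo = svfs.reference_label_combo()
        expect = sum(c * reference_matrix.values[:, j - 1] for j, c in combo.items())
        assert np.allclose(reference_dataset.b, expect)

    def test_two_class_split_is_balanced(self, reference_relations):
        spec = svfs.PlantedDatasetSpec(
            m=101, n=80, relations=reference_relations,
            label_combo={1: 1.0}, n_classes=2, seed=3,
        )
        D = svfs.plant_label(svfs.generate_planted_matrix(spec), spec)
        _, counts = np.unique(D.b, return_counts=True)
        assert len(counts) == 2 and abs(counts[0] - counts[1]) <= 1

    def test_single_term_label_couples_to_planted_cluster(self):
        # b = F5 with cluster {F5, F6}: the label row of S_[A|b] is supported
        # exactly on that cluster plus b itself (relation-vector oracle check)
        n = 9
        rels = svfs.RelationSet([{5: 1.0, 6: -2.0}], n_features=n)
        spec = svfs.PlantedDatasetSpec(
            m=20, n=n, relations=rels, label_combo={5: 1.0}, seed=4
        )
        D = svfs.plant_label(svfs.generate_planted_matrix(spec), spec)
        last = svfs.signature_matrix(D.joint_matrix()).last_row()
        support = set(np.flatnonzero(np.abs(last) > 1e-10) + 1)
        assert support == {5, 6, n + 1}
        ext = svfs.RelationSet(
            [{5: 1.0, 6: -2.0}, {5: 1.0, n + 1: -1.0}], n_features=n + 1
        )
        oracle = svfs.projection_oracle(ext)
        assert np.abs(last - oracle.S[-1]).max() < 1e-8


class TestProjectionOracle:
    def test_reference_entries(self, reference_relations):
        P = svfs.projection_oracle(reference_relations).S
        assert round(P[0, 0], 2) == 0.02
        assert np.isclose(P[0, 0], 1 / 46, atol=5e-3)
        assert round(P[5, 7], 2) == -0.44

    def test_empty_relations_zero_projector(self):
        P = svfs.projection_oracle(svfs.RelationSet([], n_features=4))
        assert np.abs(P.S).max() == 0.0

    def test_single_difference_relation(self):
        P = svfs.projection_oracle(svfs.RelationSet([{1: 1.0, 2: -1.0}], n_features=2))
        assert np.allclose(P.S, [[0.5, -0.5], [-0.5, 0.5]])


class TestMinimalRelations:
    def test_first_cluster_canonical_form(self, reference_relations):
        mr = svfs.minimal_relations(reference_relations, {1, 2, 3, 4})
        assert len(mr) == 2
        r1, r2 = mr.relations
        assert r1[1] == pytest.approx(-1.0) and r1[3] == pytest.approx(-0.5)
        assert r1[4] == pytest.approx(7.5) and 2 not in r1
        assert r2[2] == pytest.approx(-1.0) and r2[3] == pytest.approx(-1 / 6)
        assert r2[4] == pytest.approx(0.5) and 1 not in r2

    def test_singleton_cluster_empty(self, reference_relations):
        assert len(svfs.minimal_relations(reference_relations, {14})) == 0

    def test_second_cluster_spans_planted_relations(self, reference_relations):
        mr = svfs.minimal_relations(reference_relations, set(range(5, 12)))
        assert len(mr) == 5
        planted = [r for r in reference_relations.relations
                   if set(r) <= set(range(5, 12))]
        both = np.vstack([mr.as_matrix(),
                          svfs.RelationSet(planted, n_features=80).as_matrix()])
        assert np.linalg.matrix_rank(both) == 5

    def test_unclosed_cluster_errors(self, reference_relations):
        with pytest.raises(svfs.InputError, match="not closed"):
            svfs.minimal_relations(reference_relations, {1, 2})


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_oracle_matches_svd_signature(seed):
    """projection_oracle and signature_matrix agree on noiseless planted data."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 16))
    rels = random_relation_set(rng, n)
    spec = svfs.PlantedDatasetSpec(m=n + int(rng.integers(5, 15)), n=n,
                                   relations=rels, seed=seed)
    A = svfs.generate_planted_matrix(spec)
    S = svfs.signature_matrix(A)
    P = svfs.projection_oracle(rels)
    assert np.abs(S.S - P.S).max() <= 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_cross_cluster_entries_vanish_and_clusters_connect(seed):
    """Features from different planted groups always pair to a zero entry,
    and the nonzero-entry graph restricted to one group is connected."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 16))
    rels = random_relation_set(rng, n)
    P = svfs.projection_oracle(rels).S
    groups = rels.groups()
    for gi, g in enumerate(groups):
        others = [j - 1 for h in groups[gi + 1:] for j in h]
        idx = [j - 1 for j in g]
        if others:
            assert np.abs(P[np.ix_(idx, others)]).max() <= 1e-10
        sub = np.abs(P[np.ix_(idx, idx)]) > 1e-10
        np.fill_diagonal(sub, False)
        n_comp = cc_oracle(sp.csr_matrix(sub))[0]
        assert n_comp == 1
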