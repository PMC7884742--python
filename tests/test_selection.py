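"""Entropy, mutual information, and representative choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import svfs
from svfs.clustering import ClusterPartition
from svfs.linalg import FeatureMatrix
from svfs.selection import discretize


class TestEntropy:
    def test_balanced_binary_is_one_bit(self):
        assert svfs.entropy([0, 1, 0, 1]) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        assert svfs.entropy([3] * 10) == 0.0

    def test_quarter_three_quarter_split(self):
        expect = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert svfs.entropy([0, 1, 1, 1]) == pytest.approx(expect)


class TestMutualInformation:
    def test_feature_equal_to_labels_recovers_entropy(self):
        y = np.repeat([0, 1], 50)
        assert svfs.mutual_information(y.astype(float), y) == pytest.approx(
            svfs.entropy(y)
        )

    def test_perfect_dependence_one_bit(self):
        # joint distribution [[0.5, 0], [0, 0.5]]
        x = np.array([0.0, 1.0] * 20)
        y = np.array([0, 1] * 20)
        assert svfs.mutual_information(x, y) == pytest.approx(1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(42)
        m = 10_000
        x = rng.standard_normal(m)
        y = np.repeat([0, 1], m // 2)
        assert svfs.mutual_information(x, y) < 0.01

    def test_constant_feature_zero_not_error(self):
        assert svfs.mutual_information(np.ones(10), np.repeat([0, 1], 5)) == 0.0

    def test_matches_sklearn_plugin_estimator(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        y = (x + 0.5 * rng.standard_normal(200) > 0).astype(int)
        mine = svfs.mutual_information(x, y, mi_bins=6)
        ref = mutual_info_score(discretize(x, 6), y) / np.log(2)
        assert mine == pytest.approx(ref, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), m=st.integers(10, 200))
def test_mi_symmetry_and_bounds(seed, m):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 4, size=m).astype(float)
    y = rng.integers(0, 3, size=m)
    ixy = svfs.mutual_information(x, y)
    iyx = svfs.mutual_information(y.astype(float), x.astype(int))
    assert abs(ixy - iyx) <= 1e-12
    assert 0.0 <= ixy <= min(svfs.entropy(discretize(x)), svfs.entropy(y)) + 1e-12


class TestRankCandidates:
    SCORES = {"F1": 0.0364, "F2": 0.0170, "F3": 0.1093, "F4": 0.0024}

    def test_beta_exceeding_size_returns_all(self):
        out = svfs.rank_candidates(["F1", "F2", "F4"], self.SCORES, beta=5)
        assert out == ["F1", "F2", "F4"]

    def test_beta_one_returns_top(self):
        assert svfs.rank_candidates(list(self.SCORES), self.SCORES, beta=1) == ["F3"]

    def test_top_two_of_reference_cluster(self):
        assert svfs.rank_candidates(list(self.SCORES), self.SCORES, beta=2) == ["F3", "F1"]


class TestSelectRepresentatives:
    def _dataset(self, m=60, n=6, seed=0):
        rng = np.random.default_rng(seed)
        A = FeatureMatrix(values=rng.standard_normal((m, n)))
        b = (A.values[:, 0] > 0).astype(float)
        return svfs.LabeledDataset(A=A, b=b)

    def test_all_singletons_selects_everything_mi_sorted(self):
        D = self._dataset()
        part = ClusterPartition(
            clusters=tuple((j,) for j in range(6)), n_features=6
        )
        scores = {f: 1.0 for f in D.A.feature_ids}
        res = svfs.select_representatives(part, D, scores, svfs.SVFSParams(k=10))
        assert set(res.selected) == set(D.A.feature_ids)
        assert list(res.mi_values) == sorted(res.mi_values, reverse=True)
        assert res.selected[0] == "F1"  # the label-defining feature

    def test_cluster_representative_is_brute_force_mi_max(self, reference_relations):
        spec = svfs.PlantedDatasetSpec(
            m=100, n=80, relations=reference_relations,
            label_combo={1: 1.0}, n_classes=2, seed=9,
        )
        D = svfs.plant_label(svfs.generate_planted_matrix(spec), spec)
        part = ClusterPartition(
            clusters=((0, 1, 2, 3),) + tuple((j,) for j in range(4, 80)),
            n_features=80,
        )
        scores = {f: 1.0 for f in D.A.feature_ids}
        params = svfs.SVFSParams(k=80, beta=4)
        res = svfs.select_representatives(part, D, scores, params)
        rep = next(f for f in res.selected if res.cluster_of[f] == 0)
        mis = {
            f: svfs.mutual_information(D.A.column(f), D.b)
            for f in ("F1", "F2", "F3", "F4")
        }
        assert rep == max(sorted(mis), key=lambda f: (mis[f], -int(f[1:])))

    def test_reference_fixture_one_representative_per_cluster(
        self, reference_dataset
    ):
        # planted clusters {F1..F4}, {F5..F11} and the label-driving singleton F14
        part = ClusterPartition(
            clusters=(tuple(range(4)), tuple(range(4, 11)))
            + tuple((j,) for j in range(11, 80)),
            n_features=80,
        )
        ids = reference_dataset.A.feature_ids
        _, scores, _ = svfs.signature_row_filter(reference_dataset, 0.0)
        score_of = dict(zip(ids, scores))
        res = svfs.select_representatives(
            part, reference_dataset, score_of, svfs.SVFSParams(k=3)
        )
        assert len(res.selected) == 3
        clusters_hit = {res.cluster_of[f] for f in res.selected}
        assert len(clusters_hit) == 3

    def test_empty_partition_errors(self, reference_dataset):
        part = ClusterPartition(clusters=(), n_features=0)
        with pytest.raises(svfs.InputError, match="empty"):
            svfs.select_representatives(
                part, reference_dataset, {}, svfs.SVFSParams()
            )


def test_selection_deterministic_and_prefix_consistent(reference_dataset):
    params10 = svfs.SVFSParams(k=10, th_irr=0.0)
    res_a = svfs.run_svfs(reference_dataset, params10)
    res_b = svfs.run_svfs(reference_dataset, params10)
    assert res_a.selected == res_b.selected
    assert res_a.mi_values == res_b.mi_values
    res_3 = svfs.run_svfs(reference_dataset, svfs.SVFSParams(k=3, th_irr=0.0))
    assert res_3.selected == res_a.selected[:3]
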