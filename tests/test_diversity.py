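import numpy as np
import pytest

from asvnet.diversity import (DistanceMatrix, aggregate_by_rank, bray_curtis,
                              chao1, pcoa, permanova)
from asvnet.io_tables import CountMatrix
from asvnet.synthetic import SimulationConfig, generate


def _matrix(array):
    array = np.asarray(array)
    return CountMatrix([f"F{i}" for i in range(array.shape[0])],
                       [f"S{j}" for j in range(array.shape[1])], array)


class TestChao1:
    def test_no_singletons_gives_observed_richness(self):
        assert chao1([5, 5, 5]) == 3

    def test_hand_value_with_singletons_and_doubletons(self):
        # S_obs=4, F1=2, F2=1: 4 + 2*1 / (2*(1+1)) = 4.5
        assert chao1([1, 1, 2, 5]) == 4.5

    def test_zero_count_features_carry_no_information(self):
        assert chao1([1, 1, 2, 5, 0, 0]) == chao1([1, 1, 2, 5])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            chao1([0, 0])

    def test_matches_skbio_estimator(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(0)
        for _ in range(5):
            sample = rng.integers(0, 6, size=30)
            if (sample > 0).sum() == 0:
                continue
            assert chao1(sample) == pytest.approx(
                float(skbio_alpha.chao1(sample, bias_corrected=True)))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        d = bray_curtis(_matrix([[2, 2], [3, 3]]))
        assert d.matrix[0, 1] == 0

    def test_disjoint_samples_distance_one(self):
        d = bray_curtis(_matrix([[1, 0], [0, 1]]))
        assert d.matrix[0, 1] == 1

    def test_hand_value(self):
        # [2,2] vs [1,1]: 1 - 2*2/(4+2) = 1/3
        d = bray_curtis(_matrix([[2, 1], [2, 1]]))
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_bounded_and_invariant_to_zero_features(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 9, size=(8, 5))
        counts[:, 0] += 1
        base = bray_curtis(_matrix(counts))
        assert (base.matrix >= 0).all() and (base.matrix <= 1).all()
        padded = bray_curtis(_matrix(np.vstack([counts, np.zeros((3, 5), int)])))
        assert np.allclose(base.matrix, padded.matrix)


class TestPcoa:
    def test_three_equidistant_points_split_variance_evenly(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           "test")
        res = pcoa(d)
        assert res.explained.shape == (2,)
        assert np.allclose(res.explained, 0.5)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_duplicated_sample_gets_identical_coordinates(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((5, 3))
        pts[4] = pts[0]
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix([f"s{i}" for i in range(5)],
                           squareform(pdist(pts)), "euclidean")
        res = pcoa(d)
        assert np.allclose(res.coordinates[0], res.coordinates[4], atol=1e-8)

    def test_recovers_euclidean_configuration(self):
        """Classical scaling is exact on Euclidean distances: the embedded
        points reproduce the original 2-D configuration up to rotation."""
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((7, 2))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix([f"s{i}" for i in range(7)],
                           squareform(pdist(pts)), "euclidean")
        res = pcoa(d)
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-8

    def test_explained_fractions_sum_to_one(self, default_dataset):
        counts, _, _, _ = default_dataset
        res = pcoa(bray_curtis(counts))
        assert res.explained.sum() == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float), "m")
        with pytest.raises(ValueError):
            pcoa(d)


class TestPermanova:
    @staticmethod
    def _shifted_dataset(rng, n=40, shift=1.0):
        data = rng.standard_normal((n, 6))
        data[n // 2:] += shift
        from scipy.spatial.distance import pdist, squareform
        ids = [f"s{i}" for i in range(n)]
        labels = {ids[i]: ("a" if i < n // 2 else "b") for i in range(n)}
        return DistanceMatrix(ids, squareform(pdist(data)), "euclidean"), labels

    def test_power_against_planted_group_shift(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d, labels = self._shifted_dataset(rng)
            res = permanova(d, labels, n_permutations=99, seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections >= 16

    def test_p_value_plus_one_formula_never_zero(self):
        rng = np.random.default_rng(1)
        d, labels = self._shifted_dataset(rng, n=12, shift=5.0)
        res = permanova(d, labels, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_degenerate_identical_groups(self):
        d = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)), "m")
        labels = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        res = permanova(d, labels, n_permutations=49, seed=0)
        assert np.isfinite(res.pseudo_f)
        assert res.p_value == 1.0

    def test_pseudo_f_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        d, labels = self._shifted_dataset(rng, n=16, shift=0.8)
        ours = permanova(d, labels, n_permutations=9, seed=0)
        dm = skbio_distance.DistanceMatrix(d.matrix, ids=d.sample_ids)
        theirs = skbio_distance.permanova(
            dm, [labels[s] for s in d.sample_ids], permutations=9)
        assert ours.pseudo_f == pytest.approx(float(theirs["test statistic"]))

    def test_single_group_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float), "m")
        with pytest.raises(ValueError):
            permanova(d, {"a": "g", "b": "g"}, 9, 0)


class TestAggregateByRank:
    def test_family_sums(self):
        counts, taxonomy, _, truth = generate(SimulationConfig(
            n_samples=12, n_asvs=40, seed=9))
        fam = aggregate_by_rank(counts, taxonomy, "family")
        assert fam.counts.sum() <= counts.counts.sum()  # unclassified dropped
        label_of = taxonomy.rank_labels("family")
        for i, name in enumerate(fam.feature_ids):
            members = [j for j, f in enumerate(counts.feature_ids)
                       if label_of[f] == name]
            assert np.array_equal(fam.counts[i], counts.counts[members].sum(axis=0))
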