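import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asvnet.io_tables import CountMatrix
from asvnet.preprocess import (clr_transform, core_membership, css_normalize,
                               css_scale_factors, prevalence_filter,
                               rv_coefficient)


def _matrix(array, prefix="F"):
    array = np.asarray(array)
    return CountMatrix([f"{prefix}{i}" for i in range(array.shape[0])],
                       [f"S{j}" for j in range(array.shape[1])], array)


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        cm = _matrix([[1, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 1]])
        kept = prevalence_filter(cm, 2)
        assert kept.feature_ids == ["F0", "F1"]

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(10, 8))
        counts[counts < 1] = 0
        cm = _matrix(counts)
        kept = prevalence_filter(cm, 3)
        expected = [f for i, f in enumerate(cm.feature_ids)
                    if sum(1 for v in counts[i] if v > 0) >= 3]
        assert kept.feature_ids == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cm = _matrix(rng.integers(0, 4, size=(12, 6)))
        once = prevalence_filter(cm, 2)
        twice = prevalence_filter(once, 2)
        assert once.feature_ids == twice.feature_ids
        assert np.array_equal(once.counts, twice.counts)

    def test_min_samples_above_n_rejected(self):
        with pytest.raises(ValueError):
            prevalence_filter(_matrix([[1, 1]]), 3)


class TestCssNormalize:
    def test_worked_example_uniform_counts(self):
        # counts [2,2,2,2], median quantile: scale 8, normalised 250 each
        cm = _matrix([[2], [2], [2], [2]])
        out = css_normalize(cm, "fixed:0.5")
        assert np.allclose(out.values, np.log2(251.0))
        assert out.parameters["quantile"] == 0.5

    def test_scale_invariance_under_integer_multiplication(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, size=(20, 3))
        counts[0] += 1  # no all-zero sample
        doubled = counts.copy()
        doubled[:, 1] *= 5
        a = css_normalize(_matrix(counts))
        b = css_normalize(_matrix(doubled))
        assert np.allclose(a.values[:, 1], b.values[:, 1])

    def test_zero_count_maps_to_zero(self):
        out = css_normalize(_matrix([[0, 4], [5, 4], [3, 1]]))
        assert out.values[0, 0] == 0.0
        assert (out.values >= 0).all()

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="S1"):
            css_normalize(_matrix([[1, 0], [2, 0]]))

    def test_quantile_over_positive_counts_only(self):
        # with zeros dominating, the quantile must come from positives
        col = np.array([[0], [0], [0], [0], [0], [0], [10], [20], [30], [40]])
        factors = css_scale_factors(col, 0.5)
        # positive counts 10..40, median 25 -> scale = 10 + 20 = 30
        assert factors[0] == 30


class TestClr:
    def test_equal_counts_map_to_zero(self):
        out = clr_transform(_matrix([[3], [3], [3]]))
        assert np.allclose(out.values, 0.0)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(3)
        out = clr_transform(_matrix(rng.integers(0, 30, size=(15, 6))))
        assert np.allclose(out.values.sum(axis=0), 0.0, atol=1e-9)

    def test_two_feature_hand_value(self):
        # counts [1, 3], pseudocount 1: logs ln2, ln4 -> +-(ln4 - ln2)/2
        out = clr_transform(_matrix([[1], [3]]))
        expected = (np.log(4) - np.log(2)) / 2
        assert out.values[1, 0] == pytest.approx(expected, abs=1e-12)
        assert out.values[0, 0] == pytest.approx(-expected, abs=1e-12)


class TestRvCoefficient:
    def test_self_rv_is_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((10, 5))
        assert rv_coefficient(x, x) == pytest.approx(1.0)

    def test_invariant_to_orthogonal_feature_rotation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 5))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert rv_coefficient(x, x @ q) == pytest.approx(1.0, abs=1e-10)

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 12, 4))
        assert rv_coefficient(x, y) == pytest.approx(rv_coefficient(y, x))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            rv_coefficient(np.ones((5, 3)), np.random.default_rng(0).standard_normal((5, 3)))


class TestCoreMembership:
    def test_half_presence_included_at_default_threshold(self):
        cm = _matrix([[1, 1, 0, 0], [1, 0, 0, 0]])
        labels = {s: "g" for s in cm.sample_ids}
        core = core_membership(cm, labels, threshold=0.5)
        assert core.groups["g"] == {"F0"}

    def test_ubiquitous_feature_in_every_set_and_intersection(self):
        cm = _matrix([[1, 2, 3, 4], [0, 1, 0, 0]])
        labels = {"S0": "a", "S1": "a", "S2": "b", "S3": "b"}
        core = core_membership(cm, labels)
        assert "F0" in core.groups["a"] and "F0" in core.groups["b"]
        assert core.intersection == {"F0"}

    def test_matches_brute_force_per_group_tally(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 2, size=(20, 10))
        cm = _matrix(counts)
        labels = {s: ("a" if j < 6 else "b") for j, s in enumerate(cm.sample_ids)}
        core = core_membership(cm, labels, threshold=0.5)
        for group, cols in (("a", range(6)), ("b", range(6, 10))):
            expected = {
                cm.feature_ids[i]
                for i in range(20)
                if np.mean([counts[i, j] > 0 for j in cols]) >= 0.5
            }
            assert core.groups[group] == expected

    def test_unlabelled_sample_rejected(self):
        cm = _matrix([[1, 1]])
        with pytest.raises(ValueError, match="S1"):
            core_membership(cm, {"S0": "a"})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1), st.integers(2, 6))
def test_css_invariant_to_per_sample_scaling(seed, factor):
    """Multiplying one sample's counts by a positive integer leaves its
    CSS-log2 column unchanged (quantile and sum scale together)."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 20, size=(12, 4))
    counts[0] = np.maximum(counts[0], 1)
    scaled = counts.copy()
    scaled[:, 2] *= factor
    a = css_normalize(_matrix(counts))
    b = css_normalize(_matrix(scaled))
    assert np.allclose(a.values[:, 2], b.values[:, 2])
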