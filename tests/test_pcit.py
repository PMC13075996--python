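import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asvnet.io_tables import PhenotypeTable
from asvnet.pcit import (CorrelationMatrix, correlation_matrix, pcit,
                         phenotype_edges)
from asvnet.preprocess import AbundanceMatrix
from asvnet.synthetic import degenerate_fixture

from oracles import brute_force_pcit_edges
import pandas as pd


def _abundance(values, feature_ids=None):
    values = np.asarray(values, float)
    ids = feature_ids or [f"F{i}" for i in range(values.shape[0])]
    return AbundanceMatrix(ids, [f"S{j}" for j in range(values.shape[1])],
                           values, "css_log2", {})


class TestCorrelationMatrix:
    def test_identical_columns_correlate_at_one(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(8)
        corr = correlation_matrix(_abundance(np.vstack([row, row, rng.standard_normal(8)])))
        assert corr.matrix[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr.matrix), 1.0)

    def test_matches_two_pass_textbook_formula(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, 9))
        corr = correlation_matrix(_abundance(data))
        for i in range(5):
            for j in range(5):
                xi, xj = data[i], data[j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean()) ** 2).sum() *
                              ((xj - xj.mean()) ** 2).sum())
                assert corr.matrix[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_phenotype_columns_treated_like_asvs(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 10))
        pheno = PhenotypeTable(
            [f"S{j}" for j in range(10)],
            pd.DataFrame({"EFF": rng.standard_normal(10) + 1,
                          "CH4Y": rng.uniform(20, 25, 10),
                          "ACET_PROP": rng.uniform(4, 5, 10)},
                         index=[f"S{j}" for j in range(10)]))
        corr = correlation_matrix(_abundance(data), pheno)
        assert corr.node_ids[-3:] == ["EFF", "CH4Y", "ACET_PROP"]
        manual = np.corrcoef(np.vstack([data, pheno.values.T.to_numpy()]))
        assert np.allclose(corr.matrix, manual, atol=1e-12)

    def test_zero_variance_node_named_in_error(self):
        data = np.vstack([np.ones(8), np.random.default_rng(0).standard_normal(8)])
        with pytest.raises(ValueError, match="F0"):
            correlation_matrix(_abundance(data))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4"):
            correlation_matrix(_abundance(np.random.default_rng(0).standard_normal((3, 3))))


class TestPcit:
    def test_mediated_trio_indirect_edge_removed(self):
        """z drives both x and y; PCIT must drop the x-y edge and keep
        the two mediator edges."""
        cm = degenerate_fixture("mediated_trio")
        r = np.corrcoef(cm.counts.astype(float))
        net = pcit(CorrelationMatrix(["x", "y", "z"], r))
        assert net.edge_set() == {frozenset(("x", "z")), frozenset(("y", "z"))}

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_trio_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        data = rng.standard_normal((30, n))
        corr = CorrelationMatrix([f"n{i}" for i in range(n)],
                                 np.corrcoef(data, rowvar=False))
        net = pcit(corr)
        expected = {
            frozenset((f"n{i}", f"n{j}"))
            for i, j in brute_force_pcit_edges(corr.matrix)
        }
        assert net.edge_set() == expected

    def test_independent_columns_match_oracle(self):
        rng = np.random.default_rng(99)
        data = rng.standard_normal((2000, 3))
        corr = CorrelationMatrix(["a", "b", "c"], np.corrcoef(data, rowvar=False))
        net = pcit(corr)
        expected = {frozenset((corr.node_ids[i], corr.node_ids[j]))
                    for i, j in brute_force_pcit_edges(corr.matrix)}
        assert net.edge_set() == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_node_order_independence(self, seed):
        """Permuting node order then mapping labels back yields the same
        retained edge set."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        data = rng.standard_normal((25, n))
        r = np.corrcoef(data, rowvar=False)
        ids = [f"n{i}" for i in range(n)]
        base = pcit(CorrelationMatrix(ids, r)).edge_set()
        perm = rng.permutation(n)
        permuted = pcit(CorrelationMatrix([ids[i] for i in perm],
                                          r[np.ix_(perm, perm)])).edge_set()
        assert base == permuted

    def test_degenerate_perfect_correlation_trios_skipped(self):
        # two identical nodes: every trio containing them is degenerate
        rng = np.random.default_rng(5)
        base = rng.standard_normal(30)
        data = np.vstack([base, base, rng.standard_normal((2, 30))]).T
        r = np.corrcoef(data, rowvar=False)
        net = pcit(CorrelationMatrix(["a", "a2", "b", "c"], r))
        assert net.n_skipped_trios > 0
        assert frozenset(("a", "a2")) in net.edge_set()

    def test_fewer_than_three_nodes_rejected(self):
        with pytest.raises(ValueError):
            pcit(CorrelationMatrix(["a", "b"], np.eye(2)))


class TestPhenotypeEdges:
    def test_partition_and_signs(self):
        cm = degenerate_fixture("mediated_trio")
        r = np.corrcoef(cm.counts.astype(float))
        net = pcit(CorrelationMatrix(["x", "y", "EFF"], r))
        edges = phenotype_edges(net, ("EFF",))
        assert {a for a, _, _ in edges.edges["EFF"]} <= {"x", "y"}
        for _, corr_val, sign in edges.edges["EFF"]:
            assert sign == (1 if corr_val > 0 else -1)

    def test_no_incident_edges_gives_empty_sets(self):
        from asvnet.pcit import CoassocNetwork
        network = CoassocNetwork(["a", "b", "EFF"], [("a", "b", 0.5)])
        edges = phenotype_edges(network, ("EFF",))
        assert edges.edges["EFF"] == []

    def test_unknown_phenotype_rejected(self):
        from asvnet.pcit import CoassocNetwork
        network = CoassocNetwork(["a", "b"], [])
        with pytest.raises(ValueError, match="EFF"):
            phenotype_edges(network, ("EFF",))
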