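"""Partial Correlation and Information Theory (PCIT) network inference.

PCIT scans every unordered trio of nodes in a Pearson correlation
matrix.  For a trio (x, y, z) it computes the three first-order partial
correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

(and the two rotations) and a data-driven tolerance

    eps = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3,

the average ratio of partial to direct correlation.  The edge (x, y) is
flagged as indirect in this trio when |r_xy| < |eps * r_xz| and
|r_xy| < |eps * r_yz|: its correlation does not exceed the magnitude
expected if the association ran through z.  An edge is retained only if
no trio flags it, which keeps direct, conditionally independent
associations.  The scan is deterministic and independent of node order.

Trios in which any ratio denominator (a direct correlation, or a
1 - r^2 term under a square root) falls below 1e-12 carry no usable
conditional information and are skipped; a count of skipped trios is
logged.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_tables import EdgeList, PhenotypeTable
from .preprocess import AbundanceMatrix

log = logging.getLogger(__name__)

_GUARD = 1e-12


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over ASV and phenotype nodes."""

    node_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("correlation matrix shape does not match node list")
        if np.isnan(m).any():
            raise ValueError("correlation matrix contains NaN")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
        if (np.abs(m) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = np.clip(m, -1.0, 1.0)


@dataclasses.dataclass
class CoassocNetwork:
    """Edges retained by PCIT, with their Pearson correlations."""

    node_ids: list[str]
    edges: list[tuple[str, str, float]]  # node_a < node_b by list position
    n_skipped_trios: int = 0

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def to_edge_list(self, phenotype_names: tuple[str, ...]) -> EdgeList:
        rows = []
        for a, b, r in self.edges:
            n_pheno = (a in phenotype_names) + (b in phenotype_names)
            if n_pheno == 2:
                continue  # phenotype-phenotype links are not network output
            kind = "asv-phenotype" if n_pheno == 1 else "asv-asv"
            if n_pheno == 1 and a not in phenotype_names:
                a, b = b, a  # phenotype first for readability
            rows.append((a, b, r, kind))
        return EdgeList(rows)


@dataclasses.dataclass
class PhenotypeEdgeSet:
    """Per phenotype: the ASVs directly connected to it in the network."""

    edges: dict[str, list[tuple[str, float, int]]]  # phenotype -> (asv, r, sign)

    def asv_ids(self, phenotype: str) -> list[str]:
        return [asv for asv, _, _ in self.edges[phenotype]]


def correlation_matrix(abundances: AbundanceMatrix,
                       phenotypes: PhenotypeTable | None = None) -> CorrelationMatrix:
    """Pearson correlations over ASV abundances plus (optionally) the
    phenotype columns, which are treated exactly like ASV columns.
    Samples with any missing value are dropped (complete cases)."""
    data = abundances.sample_matrix()  # samples x features
    node_ids = list(abundances.feature_ids)
    if phenotypes is not None:
        pheno = phenotypes.values.loc[abundances.sample_ids].to_numpy(dtype=float)
        data = np.hstack([data, pheno])
        node_ids = node_ids + list(phenotypes.values.columns)
    complete = ~np.isnan(data).any(axis=1)
    data = data[complete]
    if data.shape[0] < 4:
        raise ValueError(f"need at least 4 complete samples, got {data.shape[0]}")
    sd = data.std(axis=0)
    if (sd == 0).any():
        bad = [node_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance nodes: {bad}")
    return CorrelationMatrix(node_ids, np.corrcoef(data, rowvar=False))


def pcit(corr: CorrelationMatrix) -> CoassocNetwork:
    """Apply the PCIT trio scan and return the retained network.

    Vectorised over the conditioning node: for each node z the partial
    correlations and tolerances of every pair (x, y) given z are computed
    with array operations; an edge is flagged whenever any trio explains
    it away.  Results are identical to a literal triple loop over trios.
    """
    r = corr.matrix
    n = r.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 nodes")
    abs_r = np.abs(r)
    one_minus_sq = 1.0 - r * r
    flagged = np.zeros((n, n), dtype=bool)
    n_skipped = 0
    idx = np.arange(n)
    for z in range(n):
        rz = r[:, z]  # r_xz for every x
        om_z = one_minus_sq[:, z]  # 1 - r_xz^2
        # square-root terms of the three partials, pairwise
        sq_xy = np.sqrt(np.maximum(np.outer(om_z, om_z), 0.0))  # for r_xy.z
        sq_y = np.sqrt(np.maximum(one_minus_sq * om_z[None, :], 0.0))  # for r_xz.y
        sq_x = np.sqrt(np.maximum(one_minus_sq * om_z[:, None], 0.0))  # for r_yz.x
        # trio validity: all denominators of the partials and tolerance ratios
        valid = (
            (abs_r > _GUARD)
            & (np.abs(rz)[:, None] > _GUARD)
            & (np.abs(rz)[None, :] > _GUARD)
            & (sq_xy > _GUARD)
            & (sq_y > _GUARD)
            & (sq_x > _GUARD)
        )
        valid &= idx[:, None] != z
        valid &= idx[None, :] != z
        valid &= idx[:, None] != idx[None, :]
        n_skipped += int(np.count_nonzero(~valid & (idx[:, None] < idx[None, :])
                                          & (idx[:, None] != z) & (idx[None, :] != z)))
        with np.errstate(divide="ignore", invalid="ignore"):
            p_xy = (r - np.outer(rz, rz)) / sq_xy
            p_xz = (rz[:, None] - r * rz[None, :]) / sq_y
            p_yz = (rz[None, :] - r * rz[:, None]) / sq_x
            eps = (p_xy / r + p_xz / rz[:, None] + p_yz / rz[None, :]) / 3.0
            cond = (abs_r < np.abs(eps * rz[:, None])) & (abs_r < np.abs(eps * rz[None, :]))
        flagged |= cond & valid
    flagged |= flagged.T
    if n_skipped:
        log.info("PCIT skipped %d degenerate trio evaluations", n_skipped)
    edges = [
        (corr.node_ids[i], corr.node_ids[j], float(r[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if r[i, j] != 0 and not flagged[i, j]
    ]
    return CoassocNetwork(list(corr.node_ids), edges, n_skipped_trios=n_skipped)


def phenotype_edges(network: CoassocNetwork,
                    phenotype_names: tuple[str, ...]) -> PhenotypeEdgeSet:
    """Partition the network's phenotype-incident edges by phenotype.
    ASV-ASV and phenotype-phenotype edges are excluded."""
    unknown = [p for p in phenotype_names if p not in network.node_ids]
    if unknown:
        raise ValueError(f"phenotype nodes not in network: {unknown}")
    pheno_set = set(phenotype_names)
    result: dict[str, list[tuple[str, float, int]]] = {p: [] for p in phenotype_names}
    for a, b, r in network.edges:
        if a in pheno_set and b in pheno_set:
            continue
        if a in pheno_set:
            result[a].append((b, r, 1 if r > 0 else -1))
        elif b in pheno_set:
            result[b].append((a, r, 1 if r > 0 else -1))
    for p in result:
        result[p].sort(key=lambda t: t[0])
    return PhenotypeEdgeSet(result)
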