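"""Alpha/beta diversity and a permutation PERMANOVA.

Chao1 richness, Bray-Curtis dissimilarity, principal coordinates
analysis on the Gower double-centred matrix, and a seeded permutation
PERMANOVA used to check batch-style grouping effects (e.g. sampling
week).  Diversity is computed on raw counts; aggregation to a taxonomy
rank (e.g. family) is available via :func:`aggregate_by_rank`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_tables import CountMatrix, TaxonomyTable, MISSING


@dataclasses.dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape does not match sample list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclasses.dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    explained: np.ndarray  # fraction of positive-eigenvalue variance per axis
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)


@dataclasses.dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


def aggregate_by_rank(counts: CountMatrix, taxonomy: TaxonomyTable,
                      rank: str = "family") -> CountMatrix:
    """Sum counts of features sharing a taxonomy label at ``rank``;
    features with a MISSING label are dropped."""
    labels = taxonomy.rank_labels(rank)
    groups: dict[str, list[int]] = {}
    for i, fid in enumerate(counts.feature_ids):
        label = labels.get(fid, MISSING)
        if label != MISSING:
            groups.setdefault(label, []).append(i)
    if not groups:
        raise ValueError(f"no features classified at rank {rank!r}")
    names = sorted(groups)
    data = np.vstack([counts.counts[groups[name]].sum(axis=0) for name in names])
    return CountMatrix(names, list(counts.sample_ids), data)


def chao1(sample_counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness:
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)), with F1/F2 the singleton and
    doubleton counts."""
    counts = np.asarray(sample_counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        raise ValueError("all-zero sample has no defined richness")
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bray_curtis(counts: CountMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity
    d(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum_i x_i + sum_i y_i)."""
    data = counts.counts.T.astype(float)  # samples x features
    if data.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (data.sum(axis=1) == 0).any():
        j = int(np.argmax(data.sum(axis=1) == 0))
        raise ValueError(f"sample {counts.sample_ids[j]!r} is all zero")
    return DistanceMatrix(list(counts.sample_ids),
                          squareform(pdist(data, metric="braycurtis")),
                          metric="braycurtis")


def pcoa(distances: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling: eigendecompose -0.5 J D^2 J with J the
    centring matrix.  Axes are ordered by eigenvalue; explained fractions
    are relative to the sum of positive eigenvalues; negative eigenvalues
    are reported but receive no coordinates (no Cailliez correction)."""
    n = len(distances.sample_ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = distances.matrix ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    explained = eigval[positive] / eigval[positive].sum()
    return PcoaResult(list(distances.sample_ids), coords, explained, eigval)


def _pseudo_f(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    n = d2.shape[0]
    a = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for members in groups:
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_between = ss_total - ss_within
    denom = ss_within / (n - a)
    if denom == 0:
        return 0.0
    return (ss_between / (a - 1)) / denom


def permanova(distances: DistanceMatrix, group_labels: dict[str, str],
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutation PERMANOVA on a distance matrix.

    The pseudo-F is built from total and within-group sums of squared
    distances; the p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    so it can never be exactly zero.
    """
    labels = [group_labels[s] for s in distances.sample_ids]
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = distances.matrix ** 2
    lab = np.array([names.index(x) for x in labels])
    groups = [np.flatnonzero(lab == g) for g in range(len(names))]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    n = len(lab)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        perm_groups = [perm[g] for g in groups]
        if _pseudo_f(d2, perm_groups) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations, seed=seed)
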