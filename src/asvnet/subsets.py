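"""Best-subset linear regression and the minimal-predictor rule.

For each model size k the search reports the predictor subset with the
highest R^2 (ordinary least squares with intercept).  The default
engine is a branch-and-bound search (Furnival-Wilson style: the R^2 of
a subset never exceeds that of any superset, so a branch whose full
completion cannot beat the incumbent at any reachable size is pruned),
which reproduces exhaustive enumeration exactly.  A forward-greedy mode
is available as an explicitly flagged fallback for large predictor
pools.  The minimal-subset rule then keeps the smallest k whose R^2
reaches a set fraction (default 95%) of the full-model R^2.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np


@dataclasses.dataclass
class SubsetPath:
    """Best predictor subset and its R^2 for each model size k = 1..p."""

    feature_ids: list[str]
    sizes: list[int]
    subsets: list[tuple[int, ...]]  # indices into feature_ids
    r2: list[float]
    search_mode: str  # exhaustive | branch_and_bound | forward

    @property
    def full_model_r2(self) -> float:
        return self.r2[-1]

    def subset_ids(self, k: int) -> list[str]:
        i = self.sizes.index(k)
        return [self.feature_ids[j] for j in self.subsets[i]]


@dataclasses.dataclass
class SelectionResult:
    minimal_k: int
    subset_ids: list[str]
    r2_selected: float
    r2_full: float
    retention: float  # r2_selected / r2_full
    reduction: float  # 1 - minimal_k / p
    threshold: float


def ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 = 1 - SSE/SST of OLS with intercept.  Rank-deficient designs
    are fit on their column space via least squares, with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 samples (n={n}, k={k})")
    design = np.hstack([np.ones((n, 1)), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; R^2 computed on the column space")
    resid = y - design @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("response has zero variance")
    return float(1.0 - (resid ** 2).sum() / sst)


class _GramR2:
    """Fast repeated subset R^2 via precomputed centred Gram matrices."""

    def __init__(self, x: np.ndarray, y: np.ndarray) -> None:
        xc = x - x.mean(axis=0, keepdims=True)
        yc = y - y.mean()
        self.gram = xc.T @ xc
        self.xy = xc.T @ yc
        self.sst = float(yc @ yc)
        if self.sst == 0:
            raise ValueError("response has zero variance")

    def r2(self, subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        idx = list(subset)
        g = self.gram[np.ix_(idx, idx)]
        c = self.xy[idx]
        beta, *_ = np.linalg.lstsq(g, c, rcond=None)
        return float(np.clip(c @ beta / self.sst, 0.0, 1.0))


def best_subsets(x: np.ndarray, y: np.ndarray, feature_ids: list[str] | None = None,
                 mode: str = "branch_and_bound", p_exhaustive_max: int = 20) -> SubsetPath:
    """Best-R^2 subset per model size.

    ``mode`` is ``exhaustive`` (full 2^p - 1 enumeration),
    ``branch_and_bound`` (identical result, pruned search),
    ``forward`` (greedy fallback, flagged in the output) or ``auto``
    (branch-and-bound up to ``p_exhaustive_max`` predictors, forward
    beyond).  R^2 ties are broken by the lexicographically smallest
    index subset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    p = x.shape[1]
    if p < 1:
        raise ValueError("need at least one predictor")
    if feature_ids is None:
        feature_ids = [f"x{i}" for i in range(p)]
    if mode == "auto":
        mode = "branch_and_bound" if p <= p_exhaustive_max else "forward"
    if mode in ("exhaustive", "branch_and_bound") and p > p_exhaustive_max:
        raise ValueError(
            f"{p} predictors exceed p_exhaustive_max={p_exhaustive_max}; "
            "raise the limit or use mode='forward'"
        )
    engine = _GramR2(x, y)
    if mode == "exhaustive":
        best = _search_exhaustive(engine, p)
    elif mode == "branch_and_bound":
        best = _search_branch_and_bound(engine, p)
    elif mode == "forward":
        best = _search_forward(engine, p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sizes = list(range(1, p + 1))
    subsets = [best[k][1] for k in sizes]
    r2 = [best[k][0] for k in sizes]
    if mode != "forward":
        for k in range(1, p):
            # monotone by construction; a violation indicates numerical failure
            assert r2[k] >= r2[k - 1] - 1e-9, "best-subset R^2 must be non-decreasing"
            r2[k] = max(r2[k], r2[k - 1])
    return SubsetPath(list(feature_ids), sizes, subsets, r2, search_mode=mode)


def _search_exhaustive(engine: _GramR2, p: int) -> dict[int, tuple[float, tuple[int, ...]]]:
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    for k in range(1, p + 1):
        for subset in itertools.combinations(range(p), k):
            r2 = engine.r2(subset)
            if k not in best or r2 > best[k][0] + 1e-15:
                best[k] = (r2, subset)
    return best


def _search_branch_and_bound(engine: _GramR2, p: int) -> dict[int, tuple[float, tuple[int, ...]]]:
    best: dict[int, tuple[float, tuple[int, ...]]] = {}

    def visit(chosen: tuple[int, ...], start: int) -> None:
        k = len(chosen)
        if k:
            r2 = engine.r2(chosen)
            if k not in best or r2 > best[k][0] + 1e-15:
                best[k] = (r2, chosen)
        remaining = tuple(range(start, p))
        if not remaining:
            return
        # Upper bound for every completion of `chosen` from `remaining`:
        # the R^2 of the union (monotone under inclusion).
        bound = engine.r2(chosen + remaining)
        lo, hi = k + 1, k + len(remaining)
        if all(kk in best and bound <= best[kk][0] + 1e-15 for kk in range(lo, hi + 1)):
            return
        for i in remaining:
            visit(chosen + (i,), i + 1)

    # Seed incumbents from a forward pass so bounds prune early.  Seeds are
    # discounted by 1e-12 so the DFS (which visits subsets in lexicographic
    # order) always replaces them with a truly visited subset, preserving the
    # smallest-subset tie-break of the exhaustive search.
    for k, (r2, subset) in _search_forward(engine, p).items():
        best[k] = (r2 - 1e-12, subset)
    visit((), 0)
    return best


def _search_forward(engine: _GramR2, p: int) -> dict[int, tuple[float, tuple[int, ...]]]:
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    chosen: list[int] = []
    available = list(range(p))
    while available:
        scores = [engine.r2(tuple(sorted(chosen + [i]))) for i in available]
        best_r2 = max(scores)
        # tie-break: smallest predictor index among maximal-R^2 additions
        pick = min(i for i, s in zip(available, scores) if s >= best_r2 - 1e-15)
        chosen.append(pick)
        available.remove(pick)
        subset = tuple(sorted(chosen))
        best[len(subset)] = (engine.r2(subset), subset)
    return best


def minimal_subset(path: SubsetPath, threshold: float = 0.95) -> SelectionResult:
    """Smallest k whose best-subset R^2 reaches ``threshold`` times the
    full-model R^2."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    r2_full = path.full_model_r2
    if r2_full == 0:
        raise ValueError("full model explains no variance; nothing to retain")
    target = threshold * r2_full
    for k, r2 in zip(path.sizes, path.r2):
        if r2 >= target:
            p = path.sizes[-1]
            return SelectionResult(
                minimal_k=k,
                subset_ids=path.subset_ids(k),
                r2_selected=r2,
                r2_full=r2_full,
                retention=r2 / r2_full,
                reduction=1.0 - k / p,
                threshold=threshold,
            )
    raise AssertionError("full model always satisfies the threshold")
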