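"""Independent reference implementations used as test oracles.

These deliberately use the most literal formulation available (triple
loops, exhaustive enumeration, explicit normal equations) and share no
code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation r_xy.z by direct evaluation."""
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))


def brute_force_pcit_edges(r: np.ndarray, guard: float = 1e-12) -> set[tuple[int, int]]:
    """Literal PCIT: loop every unordered trio, compute the three
    first-order partials and the averaged tolerance, flag edges whose
    correlation magnitude is below tolerance times both mediator
    correlations; return the retained (i < j) index pairs."""
    n = r.shape[0]
    flagged = np.zeros((n, n), dtype=bool)
    for x, y, z in itertools.combinations(range(n), 3):
        rxy, rxz, ryz = r[x, y], r[x, z], r[y, z]
        roots = [
            math.sqrt(max((1 - rxz ** 2) * (1 - ryz ** 2), 0.0)),
            math.sqrt(max((1 - rxy ** 2) * (1 - ryz ** 2), 0.0)),
            math.sqrt(max((1 - rxy ** 2) * (1 - rxz ** 2), 0.0)),
        ]
        denominators = [abs(rxy), abs(rxz), abs(ryz)] + roots
        if min(denominators) <= guard:
            continue  # degenerate trio: no flags
        pxy = (rxy - rxz * ryz) / roots[0]
        pxz = (rxz - rxy * ryz) / roots[1]
        pyz = (ryz - rxy * rxz) / roots[2]
        eps = (pxy / rxy + pxz / rxz + pyz / ryz) / 3.0
        if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
            flagged[x, y] = flagged[y, x] = True
        if abs(rxz) < abs(eps * rxy) and abs(rxz) < abs(eps * ryz):
            flagged[x, z] = flagged[z, x] = True
        if abs(ryz) < abs(eps * rxy) and abs(ryz) < abs(eps * rxz):
            flagged[y, z] = flagged[z, y] = True
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if r[i, j] != 0 and not flagged[i, j]
    }


def hypergeom_tail_by_enumeration(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) by enumerating all C(N, n) subsets of a background in
    which the first K items belong to the family."""
    hits = 0
    total = 0
    family = set(range(K))
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(family.intersection(subset)) >= x:
            hits += 1
    return hits / total


def exhaustive_best_subsets(x: np.ndarray, y: np.ndarray) -> dict[int, tuple[float, tuple[int, ...]]]:
    """Best subset per size by enumerating every subset and fitting OLS
    through explicit normal equations on the intercept-augmented design."""
    n, p = x.shape
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    sst = float(((y - y.mean()) ** 2).sum())
    for k in range(1, p + 1):
        for subset in itertools.combinations(range(p), k):
            design = np.hstack([np.ones((n, 1)), x[:, list(subset)]])
            beta = np.linalg.solve(design.T @ design, design.T @ y)
            sse = float(((y - design @ beta) ** 2).sum())
            r2 = 1.0 - sse / sst
            if k not in best or r2 > best[k][0] + 1e-15:
                best[k] = (r2, subset)
    return best
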