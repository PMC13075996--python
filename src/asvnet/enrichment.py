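"""Family-level over-representation of selected ASVs.

Given a selection of ASVs (typically those directly connected to a
phenotype in the co-association network) and a background (all ASVs in
the network), each taxonomic family is scored with the hypergeometric
upper tail P(X >= x): the probability of drawing at least x members of
the family when sampling the selection size from the background without
replacement.  The reported score is -log10 of that tail probability, so
higher scores mean stronger enrichment.  ASVs without a family
assignment are excluded from both the selection and the background
rather than pooled into a pseudo-family, since a pseudo-family would
manufacture enrichment out of classification failure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import hypergeom

from .io_tables import MISSING, TaxonomyTable


@dataclasses.dataclass
class EnrichmentResult:
    family: str
    x: int  # selected ASVs in the family
    K: int  # background family size
    n: int  # selection size (classified ASVs)
    N: int  # background size (classified ASVs)
    p_upper: float  # hypergeometric P(X >= x)
    score: float  # -log10(p_upper)
    bh_fdr: float = float("nan")  # Benjamini-Hochberg adjusted p (extra output)


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x):
        raise ValueError("invalid hypergeometric parameters")
    return float(hypergeom.sf(x - 1, N, K, n))


def family_enrichment(selected_ids: list[str], background_ids: list[str],
                      taxonomy: TaxonomyTable, min_count: int = 2) -> list[EnrichmentResult]:
    """Score each family with >= ``min_count`` selected members.

    Results are sorted by score descending (ties broken by family name).
    The default ``min_count`` of 2 reports only families hit more than
    once by the selection.
    """
    background = set(background_ids)
    stray = [s for s in selected_ids if s not in background]
    if stray:
        raise ValueError(f"selected ASVs outside the background: {stray}")
    fam = {fid: taxonomy.family(fid) for fid in background_ids}
    classified_bg = [fid for fid in background_ids if fam[fid] != MISSING]
    if not classified_bg:
        raise ValueError("no background ASV has a family assignment")
    classified_sel = [fid for fid in selected_ids if fam[fid] != MISSING]
    n_total = len(classified_bg)
    n_sel = len(classified_sel)
    bg_sizes: dict[str, int] = {}
    for fid in classified_bg:
        bg_sizes[fam[fid]] = bg_sizes.get(fam[fid], 0) + 1
    sel_sizes: dict[str, int] = {}
    for fid in classified_sel:
        sel_sizes[fam[fid]] = sel_sizes.get(fam[fid], 0) + 1
    results = []
    for family, x in sel_sizes.items():
        if x < min_count:
            continue
        p = hypergeom_upper_tail(x, n_total, bg_sizes[family], n_sel)
        results.append(EnrichmentResult(
            family=family, x=x, K=bg_sizes[family], n=n_sel, N=n_total,
            p_upper=p, score=float(-np.log10(p)) if p > 0 else float("inf"),
        ))
    # BH adjustment across the reported families (auxiliary column)
    if results:
        ps = np.array([r.p_upper for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * m / (rank_pos + 1))
            adj[i] = running
        for r, a in zip(results, adj):
            r.bh_fdr = float(a)
    results.sort(key=lambda r: (-r.score, r.family))
    return results
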