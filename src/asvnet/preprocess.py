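"""Normalisation and filtering of ASV count tables.

Counts are prevalence-filtered, then either cumulative-sum-scaling (CSS)
normalised and log2(x+1) transformed, or centred-log-ratio (CLR)
transformed.  CSS divides each sample's counts by the sum of counts not
exceeding a chosen quantile of that sample's positive counts, which
damps the influence of preferentially sequenced high-abundance taxa.
The two transforms are compared at the whole-matrix level with
Escoufier's RV coefficient.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_tables import CountMatrix

log = logging.getLogger(__name__)

CSS_SCALE = 1000.0  # scaling constant applied after division by the CSS factor


@dataclasses.dataclass
class AbundanceMatrix:
    """Real-valued transformed abundances with transform provenance.

    ``transform`` is ``"css_log2"`` or ``"clr"``; ``parameters`` records
    the quantile level / pseudocount / scaling constant actually used.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # features x samples
    transform: str
    parameters: dict

    def sample_matrix(self, feature_ids: list[str] | None = None) -> np.ndarray:
        """Samples-by-features view, optionally restricted to ``feature_ids``."""
        if feature_ids is None:
            return self.values.T
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        return self.values[rows].T


@dataclasses.dataclass
class CoreMembership:
    """Per-group sets of features present in at least ``threshold`` of
    the group's samples, plus the intersection across all groups."""

    threshold: float
    groups: dict[str, set[str]]
    intersection: set[str]


def prevalence_filter(counts: CountMatrix, min_samples: int) -> CountMatrix:
    """Keep features observed (count > 0) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    n_samples = len(counts.sample_ids)
    if min_samples > n_samples:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {n_samples}")
    prevalence = (counts.counts > 0).sum(axis=1)
    keep = prevalence >= min_samples
    kept_ids = [f for f, k in zip(counts.feature_ids, keep) if k]
    if not kept_ids:
        raise ValueError("prevalence filter removed every feature")
    return CountMatrix(kept_ids, list(counts.sample_ids), counts.counts[keep])


def css_scale_factors(counts: np.ndarray, quantile: float) -> np.ndarray:
    """Per-sample CSS factor: sum of counts not exceeding the ``quantile``
    level of that sample's positive counts (linear-interpolation quantile)."""
    n_samples = counts.shape[1]
    factors = np.empty(n_samples)
    for j in range(n_samples):
        col = counts[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(f"sample index {j} has no positive counts")
        q = np.quantile(positive, quantile)
        factors[j] = col[col <= q].sum()
    return factors


def choose_css_quantile(counts: np.ndarray, grid_step: float = 0.05,
                        instability: float = 0.1) -> float:
    """Data-driven quantile level: the smallest level at which the median
    scale factor across samples changes by more than ``instability``
    (relative) from one grid point to the next.  Falls back to 0.5 when
    the median scale stays stable over the whole grid."""
    levels = np.arange(grid_step, 1.0, grid_step)
    medians = np.array([np.median(css_scale_factors(counts, lv)) for lv in levels])
    for i in range(len(levels) - 1):
        if medians[i] > 0 and abs(medians[i + 1] - medians[i]) / medians[i] > instability:
            return float(levels[i])
    return 0.5


def css_normalize(counts: CountMatrix, quantile_mode: str = "fixed:0.5") -> AbundanceMatrix:
    """CSS-normalise then log2(x+1) transform.

    ``quantile_mode`` is ``"fixed:<level>"`` or ``"adaptive"``.  For
    sample j with quantile level l, the scale is
    ``s_j = sum of counts <= q_j(l)`` with q over positive counts; the
    normalised value is ``count / s_j * 1000`` and the output is
    ``log2(normalised + 1)``, so zero counts map to zero.
    """
    data = counts.counts.astype(float)
    if (data.sum(axis=0) == 0).any():
        j = int(np.argmax(data.sum(axis=0) == 0))
        raise ValueError(f"sample {counts.sample_ids[j]!r} is all zero")
    if quantile_mode == "adaptive":
        level = choose_css_quantile(counts.counts)
    elif quantile_mode.startswith("fixed:"):
        level = float(quantile_mode.split(":", 1)[1])
        if not 0 < level < 1:
            raise ValueError(f"quantile level {level} outside (0,1)")
    else:
        raise ValueError(f"unknown quantile_mode {quantile_mode!r}")
    factors = css_scale_factors(counts.counts, level)
    if (factors == 0).any():
        j = int(np.argmax(factors == 0))
        raise ValueError(f"sample {counts.sample_ids[j]!r} has CSS scale factor 0")
    values = np.log2(data / factors[None, :] * CSS_SCALE + 1.0)
    return AbundanceMatrix(
        list(counts.feature_ids),
        list(counts.sample_ids),
        values,
        transform="css_log2",
        parameters={"quantile": level, "scale": CSS_SCALE, "mode": quantile_mode},
    )


def clr_transform(counts: CountMatrix, pseudocount: float = 1.0) -> AbundanceMatrix:
    """Centred log-ratio: natural log(count + pseudocount) minus each
    sample's mean log, so every sample column sums to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(counts.counts.astype(float) + pseudocount)
    values = logs - logs.mean(axis=0, keepdims=True)
    return AbundanceMatrix(
        list(counts.feature_ids),
        list(counts.sample_ids),
        values,
        transform="clr",
        parameters={"pseudocount": pseudocount},
    )


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Escoufier's RV between two samples-by-features matrices sharing the
    same sample set.  Columns are centred internally; the coefficient is
    trace(XX'YY') / sqrt(trace((XX')^2) trace((YY')^2)), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("matrices must share the sample dimension")
    xc = x - x.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    gx = xc @ xc.T
    gy = yc @ yc.T
    denom = np.sqrt((gx * gx).sum() * (gy * gy).sum())
    if denom == 0:
        raise ValueError("RV undefined for a zero-variance matrix")
    return float((gx * gy).sum() / denom)


def core_membership(counts: CountMatrix, group_labels: dict[str, str],
                    threshold: float = 0.5) -> CoreMembership:
    """Features present (count > 0) in at least ``threshold`` fraction of
    each group's samples; the across-group intersection is also reported."""
    unlabelled = [s for s in counts.sample_ids if s not in group_labels]
    if unlabelled:
        raise ValueError(f"samples without a group label: {unlabelled}")
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(counts.sample_ids):
        groups.setdefault(group_labels[s], []).append(j)
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    present = counts.counts > 0
    sets: dict[str, set[str]] = {}
    for name, cols in groups.items():
        frac = present[:, cols].mean(axis=1)
        sets[name] = {f for f, ok in zip(counts.feature_ids, frac >= threshold) if ok}
    intersection = set.intersection(*sets.values()) if sets else set()
    return CoreMembership(threshold=threshold, groups=sets, intersection=intersection)
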