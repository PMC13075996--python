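"""Random baselines, cross-validation and summary statistics.

The random baseline refits the regression on repeated random draws of
the same number of ASVs from the full prevalence-filtered pool, to
check that network-selected predictors beat untargeted ones.  Predictive
ability is assessed with k-fold cross-validation, where CV-R^2 is the
square of the Pearson correlation between observed phenotypes and
held-out predictions (deliberately not 1 - SSE/SST, which differs
out of sample).  :func:`summarize` derives the improvement, retention
and reduction columns reported for trait x dataset combinations.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .subsets import ols_r2


@dataclasses.dataclass
class BaselineResult:
    n_features: int
    r2_draws: list[float]
    mean_r2: float
    seed: int


@dataclasses.dataclass
class CVResult:
    fold_assignment: np.ndarray  # fold index per sample
    fold_r2: list[float]  # NaN where the held-out response was constant
    mean_cv_r2: float
    seed: int


def random_baseline(pool_ids: list[str], abundance_lookup, y: np.ndarray, m: int,
                    n_draws: int = 10, seed: int = 0,
                    exclude_ids: list[str] | None = None) -> BaselineResult:
    """Mean R^2 of ``n_draws`` random size-``m`` ASV sets.

    ``abundance_lookup(ids)`` must return a samples-by-len(ids) matrix
    (e.g. ``AbundanceMatrix.sample_matrix``).  By default draws come from
    the full pool; ``exclude_ids`` optionally removes e.g. the
    network-selected ASVs first.
    """
    pool = list(pool_ids)
    if exclude_ids:
        drop = set(exclude_ids)
        pool = [p for p in pool if p not in drop]
    if m > len(pool):
        raise ValueError(f"cannot draw {m} ASVs from a pool of {len(pool)}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        ids = list(rng.choice(pool, size=m, replace=False))
        draws.append(ols_r2(abundance_lookup(ids), y))
    return BaselineResult(n_features=m, r2_draws=draws,
                          mean_r2=float(np.mean(draws)), seed=seed)


def kfold_cv(x: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0) -> CVResult:
    """Single k-fold split: seeded shuffle, round-robin fold assignment,
    OLS fit per training set, CV-R^2 = squared Pearson correlation of
    observed vs predicted in the held-out fold."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} samples, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    fold_r2: list[float] = []
    for f in range(k):
        test = folds == f
        train = ~test
        design = np.hstack([np.ones((train.sum(), 1)), x[train]])
        coef, *_ = np.linalg.lstsq(design, y[train], rcond=None)
        pred = np.hstack([np.ones((test.sum(), 1)), x[test]]) @ coef
        observed = y[test]
        if np.std(observed) == 0 or np.std(pred) == 0:
            warnings.warn(f"fold {f}: constant observed or predicted values; "
                          "CV-R^2 undefined for this fold")
            fold_r2.append(float("nan"))
            continue
        r, _ = pearsonr(observed, pred)
        fold_r2.append(float(r) ** 2)
    mean = float(np.nanmean(fold_r2))
    return CVResult(fold_assignment=folds, fold_r2=fold_r2, mean_cv_r2=mean, seed=seed)


#: base columns required by :func:`summarize`
BASE_COLUMNS = ["dataset", "trait", "n_full", "r2_full", "r2_random_mean",
                "n_selected", "r2_selected"]


def summarize(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Derive per-row improvement/retention/reduction columns and the
    aggregate statistics over trait x dataset rows.

    Derived columns:
      improvement_full     = r2_full - r2_random_mean
      improvement_selected = r2_selected - r2_random_mean
      retention_pct        = 100 * r2_selected / r2_full
      reduction_pct        = 100 * (1 - n_selected / n_full)
    """
    missing = [c for c in BASE_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"missing base columns: {missing}")
    table = rows.copy()
    table["improvement_full"] = table["r2_full"] - table["r2_random_mean"]
    table["improvement_selected"] = table["r2_selected"] - table["r2_random_mean"]
    table["retention_pct"] = 100.0 * table["r2_selected"] / table["r2_full"]
    table["reduction_pct"] = 100.0 * (1.0 - table["n_selected"] / table["n_full"])
    aggregates = {
        "mean_improvement_full": float(table["improvement_full"].mean()),
        "min_improvement_full": float(table["improvement_full"].min()),
        "max_improvement_full": float(table["improvement_full"].max()),
        "min_improvement_selected": float(table["improvement_selected"].min()),
        "max_improvement_selected": float(table["improvement_selected"].max()),
        "min_retention_pct": float(table["retention_pct"].min()),
        "max_retention_pct": float(table["retention_pct"].max()),
        "min_reduction_pct": float(table["reduction_pct"].min()),
        "max_reduction_pct": float(table["reduction_pct"].max()),
    }
    return table, aggregates
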