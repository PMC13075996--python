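"""Published reference values used in worked examples.

These numbers come from a published cattle study comparing
network-selected against randomly selected ASVs as predictors of feed
efficiency (EFF), methane yield (CH4Y) and the acetate:propionate ratio
(ACET_PROP) in four datasets: Charolais rumen (CHA_Ru), Charolais
faeces (CHA_Fe), Holstein rumen (HOL_Ru) and Holstein faeces (HOL_Fe).
For each trait x dataset combination the table lists the number of
ASVs directly connected to the phenotype in the co-association network
and the model-fit R^2 of the full model, the mean R^2 of ten random
same-size draws, and the minimal subset retained by the ~95% rule with
its R^2.  They serve as worked-example inputs for the summary
arithmetic in :func:`asvnet.evaluation.summarize`; reproducing the
R^2 values themselves requires the original sequence data.
"""

from __future__ import annotations

import pandas as pd

#: dataset, trait, N full, R2 full, R2 random (mean of 10 draws), N selected, R2 selected
REPORTED_REGRESSION_ROWS: list[tuple[str, str, int, float, float, int, float]] = [
    ("CHA_Ru", "EFF", 19, 0.61, 0.36, 8, 0.58),
    ("CHA_Ru", "CH4Y", 22, 0.62, 0.39, 11, 0.59),
    ("CHA_Ru", "ACET_PROP", 36, 0.88, 0.71, 17, 0.84),
    ("CHA_Fe", "EFF", 13, 0.63, 0.19, 8, 0.59),
    ("CHA_Fe", "CH4Y", 13, 0.59, 0.24, 7, 0.56),
    ("CHA_Fe", "ACET_PROP", 13, 0.57, 0.25, 6, 0.54),
    ("HOL_Ru", "EFF", 14, 0.70, 0.26, 8, 0.66),
    ("HOL_Ru", "CH4Y", 20, 0.63, 0.36, 7, 0.60),
    ("HOL_Ru", "ACET_PROP", 28, 0.81, 0.54, 15, 0.76),
    ("HOL_Fe", "EFF", 11, 0.47, 0.20, 7, 0.45),
    ("HOL_Fe", "CH4Y", 17, 0.69, 0.33, 9, 0.65),
    ("HOL_Fe", "ACET_PROP", 12, 0.61, 0.22, 8, 0.58),
]

#: per-fold CV-R^2 reported for EFF in Charolais faeces (5-fold split)
REPORTED_CV_FOLDS_CHA_FE_EFF: tuple[float, ...] = (0.47, 0.42, 0.33, 0.70, 0.76)

#: published phenotype summary statistics (mean, SD) per herd
REPORTED_PHENOTYPE_STATS = {
    "charolais": {"EFF": (0.97, 0.22), "CH4Y": (24.95, 4.11), "ACET_PROP": (4.92, 0.42)},
    "holstein": {"EFF": (1.46, 0.15), "CH4Y": (22.99, 2.20), "ACET_PROP": (4.17, 0.40)},
}


def reported_regression_table() -> pd.DataFrame:
    """The published regression comparison as a DataFrame with the base
    columns expected by :func:`asvnet.evaluation.summarize`."""
    return pd.DataFrame(
        REPORTED_REGRESSION_ROWS,
        columns=["dataset", "trait", "n_full", "r2_full",
                 "r2_random_mean", "n_selected", "r2_selected"],
    )
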