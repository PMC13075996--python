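"""Summary arithmetic on the published trait x dataset comparison.

Feeds the published regression table (full model, random selection,
minimal selection per trait and dataset) through the summary layer and
prints the aggregate statistics: how much network selection improves on
random ASV sets and how much the retention rule shrinks the models.
"""

import numpy as np

from asvnet.evaluation import summarize
from asvnet.reference import (REPORTED_CV_FOLDS_CHA_FE_EFF,
                              reported_regression_table)

table, agg = summarize(reported_regression_table())
print(table[["dataset", "trait", "improvement_full", "retention_pct",
             "reduction_pct"]].round(2).to_string(index=False))
print()
print(f"mean full-vs-random improvement: {agg['mean_improvement_full']:.2f} R^2 units")
print(f"max  full-vs-random improvement: {agg['max_improvement_full']:.2f}")
print(f"min  selected-vs-random improvement: {agg['min_improvement_selected']:.2f}")
print(f"ASV reduction range: {agg['min_reduction_pct']:.0f}%-"
      f"{agg['max_reduction_pct']:.0f}%")
print(f"retention range: {agg['min_retention_pct']:.0f}%-"
      f"{agg['max_retention_pct']:.0f}%")
print(f"mean CV-R^2 from the published EFF fold values: "
      f"{np.mean(REPORTED_CV_FOLDS_CHA_FE_EFF):.2f}")
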