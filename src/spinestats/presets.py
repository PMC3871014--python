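"""Published reference tables from the three-replicate dissociated
hippocampal culture study (DIV 7/14/21) that this package's analyses target.

These desk-scale constants let users reproduce the study's worked examples —
the experiment-by-type chi-square, the multinomial-logistic prediction
probabilities, and the Bayes factors — without access to the raw image data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Neurons collected per experiment (rows 1-3) and DIV (columns 7, 14, 21).
NEURON_COUNTS = pd.DataFrame(
    [[8, 9, 7], [10, 10, 10], [7, 7, 7]],
    index=pd.Index([1, 2, 3], name="experiment"),
    columns=pd.Index([7, 14, 21], name="div"),
)

#: Spine counts per experiment and type.
SPINE_TYPE_COUNTS = pd.DataFrame(
    [[4035, 3224, 1915], [5400, 6619, 2570], [2388, 3485, 649]],
    index=pd.Index([1, 2, 3], name="experiment"),
    columns=pd.Index(["mushroom", "stubby", "thin"], name="type"),
)

#: Quartile breakpoints (μm) of pooled soma distance used for SD binning.
SD_QUARTILE_BREAKS = (65.65, 108.99, 157.04)

#: Multinomial-logistic coefficients per experiment (mushroom is the
#: reference category).  Row order: stubby, thin.  Column order matches the
#: feature vector (intercept, N1-Var1, N1-Var2, N2-Var1, N2-Var2, N3-Var1,
#: N3-Var2, DIV).
MLR_COEFFICIENT_COLUMNS = (
    "intercept",
    "N1-Var1",
    "N1-Var2",
    "N2-Var1",
    "N2-Var2",
    "N3-Var1",
    "N3-Var2",
    "DIV",
)

MLR_COEFFICIENTS = {
    1: np.array(
        [
            [0.06, 0.04, 0.47, -0.52, 0.10, 0.09, 0.25, -0.01],  # stubby
            [1.05, -0.57, -0.34, -0.84, -0.57, -0.23, -0.32, 0.00],  # thin
        ]
    ),
    2: np.array(
        [
            [0.08, 0.03, 0.67, -0.14, 0.05, -0.20, -0.09, -0.02],
            [0.25, -0.76, -0.17, -0.61, -0.37, -0.06, -0.05, -0.02],
        ]
    ),
    3: np.array(
        [
            [-0.36, -0.24, 0.33, -0.14, 0.19, -0.03, 0.30, 0.01],
            [0.35, -0.66, -0.58, -0.33, -0.28, -0.25, -0.33, -0.02],
        ]
    ),
}


def type_priors(experiment: int) -> dict[str, float]:
    """Base-rate type frequencies for one experiment from the published counts."""
    row = SPINE_TYPE_COUNTS.loc[experiment]
    total = row.sum()
    return {t: float(row[t] / total) for t in row.index}
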