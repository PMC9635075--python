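"""Published reference values used by the verification harness.

These are the *inputs* reported by the clinical validation study of nocturnal
limb accelerations in chronic spinal cord injury (40 adults, ankle + wrist
accelerometry over 1-5 nights): the selected-feature counts, raw R-squared
and MSE values of the strength and sensation models, the spasticity
confusion matrix, and the covariates-only vs covariates+LA adjusted-R-squared
pairs. The verification harness (``limbacc.verify`` / ``limbacc table2-check``)
recomputes every derived statistic from these inputs with
:mod:`limbacc.evaluation` and compares against the values the study printed.
"""

from __future__ import annotations

import numpy as np

#: sample size of the strength / sensation regressions
N_REGRESSION = 40
#: sample size of the spasticity classification (two participants enrolled
#: before the spasticity measure was added)
N_CLASSIFICATION = 38

#: (features selected, printed R2, printed MAE, printed MSE) per outcome
REGRESSION_INPUTS = {
    "strength": {"p": 16, "r2": 0.687, "mae": 9.17, "mse": 93.56},
    "sensation": {"p": 15, "r2": 0.733, "mae": 2.91, "mse": 13.32},
}

#: printed derived values for the same rows
REGRESSION_PRINTED = {
    "strength": {"adj_r2": 0.469, "f2": 0.88, "rmse": 9.67},
    "sensation": {"adj_r2": 0.566, "f2": 1.31, "rmse": 3.65},
}

SPASTICITY_CLASSES = ("none", "mild", "moderate")

#: rows = actual, columns = predicted, class order none/mild/moderate
SPASTICITY_CONFUSION = np.array(
    [
        [14, 1, 0],
        [3, 11, 0],
        [1, 2, 6],
    ]
)

SPASTICITY_PRINTED = {
    "oca": 0.816,
    "f1": {"none": 0.848, "mild": 0.786, "moderate": 0.800},
    "precision": {"none": 0.778, "mild": 0.786, "moderate": 1.000},
    "recall": {"none": 0.933, "mild": 0.786, "moderate": 0.667},
    "macro": {"f1": 0.811, "precision": 0.854, "recall": 0.795},
    "weighted": {"f1": 0.814, "precision": 0.833, "recall": 0.816},
}

#: covariates-only vs covariates+LA adjusted R2: (full adj R2, printed delta,
#: printed percent increase). The reduced-model adj R2 is full - delta.
SUPPLEMENTAL_DELTAS = {
    "strength": {"adj_r2_full": 0.847, "delta": 0.355, "pct": 72.0},
    "sensation": {"adj_r2_full": 0.714, "delta": 0.492, "pct": 222.0},
}
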