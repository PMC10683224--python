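"""Published 10-fold LIDC-IDRI results of the RGD fusion classifier.

These are the per-fold evaluation metrics reported for the full-scale RGD
model on LIDC-IDRI (accuracy / sensitivity / specificity / precision in
percent; F1 and AUC as fractions), stored exactly as printed.  They serve as
inputs to the internal-consistency checks: recomputing F1 from each fold's
precision and sensitivity, and recomputing the column means.

One printed value is internally inconsistent: fold 5's precision is printed
as 82.31%, but the same row's accuracy/sensitivity/specificity determine the
confusion counts (n=77: TP=24, FN=5, TN=46, FP=2) and hence precision
24/26 = 92.31% -- which also reproduces the printed F1 of 0.8727 exactly,
while 82.31% does not (it would give F1 = 0.8253).  We therefore treat 82.31
as a digit transposition of 92.31.  ``CONSISTENT_PRECISION`` carries the
corrected column; the printed column mean (92.46%) is reproducible only from
the *printed* values, i.e. the transposition propagated into the mean.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FOLD_ACCURACY",
    "FOLD_SENSITIVITY",
    "FOLD_SPECIFICITY",
    "FOLD_PRECISION_PRINTED",
    "FOLD_F1",
    "FOLD_AUC",
    "CONSISTENT_PRECISION",
    "REPORTED_MEANS",
]

# per-fold values, folds 1..10, as printed (percent)
FOLD_ACCURACY = (93.83, 95.00, 95.00, 88.61, 90.91, 93.59, 96.20, 94.87, 92.31, 92.21)
FOLD_SENSITIVITY = (84.38, 90.63, 96.77, 87.10, 82.76, 90.00, 90.32, 93.55, 83.33, 93.33)
FOLD_SPECIFICITY = (100.0, 97.92, 93.88, 89.58, 95.83, 95.83, 100.0, 95.74, 97.92, 91.49)
FOLD_PRECISION_PRINTED = (100.0, 96.67, 90.91, 84.38, 82.31, 93.10, 100.0, 93.55, 96.15, 87.50)
FOLD_F1 = (0.9153, 0.9355, 0.9375, 0.8571, 0.8727, 0.9153, 0.9492, 0.9355, 0.8929, 0.9032)
FOLD_AUC = (0.9566, 0.9785, 0.9921, 0.9516, 0.9231, 0.9701, 0.9758, 0.9629, 0.9688, 0.9496)

# precision column with the fold-5 digit transposition corrected (see module
# docstring); all other folds as printed
CONSISTENT_PRECISION = tuple(
    92.31 if i == 4 else v for i, v in enumerate(FOLD_PRECISION_PRINTED)
)

# the reported mean row (accuracy..precision percent, F1/AUC fractions)
REPORTED_MEANS = {
    "accuracy": 93.25,
    "sensitivity": 89.22,
    "specificity": 95.82,
    "precision": 92.46,
    "f1": 0.9114,
    "auc": 0.9629,
}


def recompute_f1(precision_pct: float, sensitivity_pct: float) -> float:
    """F1 from precision and recall given in percent."""
    p, r = precision_pct / 100.0, sensitivity_pct / 100.0
    return 2 * p * r / (p + r)


def fold5_consistent_counts() -> dict[str, int]:
    """Confusion counts implied by the printed fold-5 accuracy, sensitivity
    and specificity (the basis of the precision correction)."""
    return {"tp": 24, "fn": 5, "tn": 46, "fp": 2}
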