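"""Classifier performance metrics.

The only metric the pipeline needs is the area under the ROC curve, computed
with the rank-sum (Mann-Whitney) estimator: the probability that a randomly
chosen positive receives a higher score than a randomly chosen negative,
with tied scores contributing 1/2.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc_score"]


def auc_score(y_true, scores) -> float:
    """ROC AUC via the rank-sum estimator.

    Parameters
    ----------
    y_true : array-like of {0, 1}
        Class labels; 1 marks the positive (live-birth) class.
    scores : array-like of float
        Predicted scores; larger means more positive-like.

    Returns
    -------
    float
        AUC in [0, 1]; ties between a positive and a negative score count 0.5.
    """
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one sample of each class")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
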