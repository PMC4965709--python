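"""Ranking metrics: AUC (Mann-Whitney form) and area under the
precision-recall curve.

AUC is the probability that a uniformly chosen positive outscores a
uniformly chosen negative, with ties counting one half — computed from
average ranks, which is exactly the normalized Mann-Whitney U statistic.

AUPR follows a descending-score sweep: scores are processed in tied
blocks, and each block contributes its recall increment times the
precision at the block boundary (step-wise interpolation, the
average-precision convention). Requesting either metric on single-class
labels raises rather than returning a placebo value.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError


def _split(scores, labels=None):
    if labels is None:  # list of (score, label) pairs
        arr = np.asarray([(s, l) for s, l in scores], dtype=float)
        if arr.size == 0:
            raise UndefinedMetricError("empty score list")
        return arr[:, 0], arr[:, 1] > 0
    return np.asarray(scores, dtype=float), np.asarray(labels) > 0


def auc(scores, labels=None) -> float:
    """Rank-based ROC AUC with the tie-as-half convention.

    Accepts either a list of ``(score, label)`` pairs or separate
    score/label arrays. Labels are truthy for positives.
    """
    s, pos = _split(scores, labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined with {n_pos} positives and {n_neg} negatives"
        )
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores, labels=None) -> float:
    """Area under the precision-recall curve by descending-score sweep."""
    s, pos = _split(scores, labels)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPR undefined without positives")
    order = np.argsort(-s, kind="stable")
    s, pos = s[order], pos[order]
    # block boundaries: last index of each tied-score group
    boundary = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    tp = np.cumsum(pos)[boundary]
    n_seen = boundary + 1
    precision = tp / n_seen
    recall = tp / n_pos
    d_recall = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(d_recall * precision))
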