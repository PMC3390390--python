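"""Shared ranking metrics (one tie convention everywhere)."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["mann_whitney_auroc"]


def mann_whitney_auroc(pos_scores, neg_scores) -> float:
    """AUROC of ranking positives above negatives, ties counting 1/2.

    Computed as the Mann-Whitney U statistic over n1*n2 via midranks,
    which equals the trapezoidal area under the ROC curve of the pooled
    ranking. Raises ValueError when either class is empty.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty to compute AUROC")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
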