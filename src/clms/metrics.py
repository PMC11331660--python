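"""Discrimination metrics: AUROC, its site-size-weighted average, and
forgetting-trajectory summaries.

AUROC is computed from the rank statistic (Mann-Whitney U with midrank tie
handling), i.e. the probability that a uniformly drawn positive outranks a
uniformly drawn negative, ties credited 1/2.  This agrees exactly with a
brute-force scan over all positive-negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class SiteMetric:
    site_id: str
    n: int
    auroc: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("site size must be >= 1")


def auroc(scores, labels) -> float:
    """Rank-based AUROC for binary labels; raises if only one class present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks for ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def weighted_auroc(site_metrics: list[SiteMetric]) -> float:
    """Size-weighted average AUROC, Σ_i (N_i / N) · AUROC_i."""
    if not site_metrics:
        raise ValueError("need at least one site metric")
    total = sum(m.n for m in site_metrics)
    return float(sum(m.n / total * m.auroc for m in site_metrics))


def forgetting_trajectory(stage_metrics) -> list[dict]:
    """Summarize a (stages × sites) AUROC matrix per site.

    Returns one dict per site with the peak over stages, the final-stage
    value, and the drop (peak − final, always ≥ 0).
    """
    m = np.asarray(stage_metrics, dtype=float)
    if m.ndim != 2:
        raise ValueError("stage_metrics must be a 2-D stages × sites matrix")
    out = []
    for j in range(m.shape[1]):
        col = m[:, j]
        peak = float(col.max())
        final = float(col[-1])
        out.append({"site": j, "peak": peak, "final": final, "drop": peak - final})
    return out
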