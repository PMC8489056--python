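"""Comparative ΔCq reference-gene stability.

For every ordered gene pair (j, k) the per-sample difference
ΔCq_s = Cq_js − Cq_ks is formed; a stable pair keeps a constant offset, so
its ΔCq has low standard deviation.  A gene's stability score is the mean
of the SDs of its pairwise differences against every other candidate;
genes are ranked ascending (lower = more stable).  Because the score is
built entirely from within-sample differences it is exactly invariant to
any per-sample shift common to all genes (RNA loading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ranks_ascending, sample_sd
from .cq_data import CqMatrix, InsufficientDataError

__all__ = ["DeltaCqResult", "delta_cq_stability"]


@dataclass
class DeltaCqResult:
    """Per-gene comparative ΔCq stability score and rank."""

    gene: str
    mean_pair_sd: float  # cycles
    rank: int


def delta_cq_stability(m: CqMatrix) -> list[DeltaCqResult]:
    """Rank genes by the mean SD of pairwise Cq differences.

    Requires a complete matrix with >= 2 genes and >= 3 samples.  SDs use
    the n−1 denominator; ranking ties are broken by input gene order.
    """
    values = m.values
    if values.isna().any().any():
        raise InsufficientDataError(
            "delta_cq_stability requires a complete matrix; "
            "take a complete-case submatrix first"
        )
    genes = list(values.index)
    G = len(genes)
    if G < 2:
        raise InsufficientDataError("need >= 2 genes")
    if values.shape[1] < 3:
        raise InsufficientDataError("need >= 3 samples")

    x = values.to_numpy(dtype=float)  # gene x sample
    # pair_sd[j, k] = SD over samples of (Cq_j - Cq_k); symmetric, 0 diagonal
    pair_sd = np.zeros((G, G))
    for j in range(G):
        for k in range(j + 1, G):
            sd = float(sample_sd(x[j] - x[k]))
            pair_sd[j, k] = pair_sd[k, j] = sd

    scores = pair_sd.sum(axis=1) / (G - 1)
    ranks = ranks_ascending(scores)
    return [
        DeltaCqResult(gene=g, mean_pair_sd=float(scores[i]), rank=int(ranks[i]))
        for i, g in enumerate(genes)
    ]


def results_frame(results: list[DeltaCqResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "mean_pair_sd": [r.mean_pair_sd for r in results],
            "rank": [r.rank for r in results],
        }
    ).set_index("gene")
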