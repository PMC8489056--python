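"""Consensus reference-gene ranking by geometric mean of method ranks.

Each stability algorithm produces its own ordering; the comprehensive
ranking aggregates them with the unweighted geometric mean of each gene's
per-method ranks (tied positions receive average ranks).  Lower geometric
mean = more stable overall.  This is the documented, reproducible
aggregation rule; web tools that integrate the same four algorithms have
been observed to apply undocumented weighting, so their printed values may
differ from this rule even on identical inputs — reports surface the rule
used rather than reverse-engineering any particular tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConsensusResult", "aggregate_rankings", "ranks_with_ties"]


@dataclass
class ConsensusResult:
    gene: str
    method_ranks: dict[str, float]
    geomean_rank: float
    final_rank: int


def ranks_with_ties(scores: dict[str, float]) -> dict[str, float]:
    """Average-rank a score mapping ascending (competition-free ties)."""
    s = pd.Series(scores)
    return s.rank(method="average").to_dict()


def aggregate_rankings(
    rankings: dict[str, dict[str, float]]
) -> list[ConsensusResult]:
    """Aggregate per-method rank mappings into a consensus ordering.

    ``rankings`` maps method name -> {gene: rank}, where ranks may already
    carry average-rank ties.  Every method must rank the identical gene
    set.  Genes are ordered ascending by the geometric mean of their
    ranks; ties in the final ordering are broken by gene input order
    (taken from the first method's mapping).
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    methods = list(rankings)
    genes = list(rankings[methods[0]])
    gene_set = set(genes)
    for method in methods:
        if set(rankings[method]) != gene_set:
            missing = gene_set.symmetric_difference(rankings[method])
            raise ValueError(
                f"method {method!r} ranks a different gene set (mismatch: {sorted(missing)})"
            )

    geomeans = {
        g: float(np.exp(np.mean([np.log(rankings[m][g]) for m in methods])))
        for g in genes
    }
    order = sorted(genes, key=lambda g: (geomeans[g], genes.index(g)))
    final_rank = {g: i + 1 for i, g in enumerate(order)}
    return [
        ConsensusResult(
            gene=g,
            method_ranks={m: float(rankings[m][g]) for m in methods},
            geomean_rank=geomeans[g],
            final_rank=final_rank[g],
        )
        for g in genes
    ]
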