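"""geNorm expression-stability analysis.

Cq values are first transformed to relative quantities q = E^(Cq_min − Cq)
per gene (the minimum-Cq sample is the calibrator at q = 1; the default
efficiency E = 2 gives the classical 2^−ΔCq transform).  For a gene pair
(j, k) the spread of log2(q_j/q_k) across samples measures how differently
the two genes behave; a gene's M value is the mean of these pairwise
spreads against all other candidates.  Lower M = more stable; M = 1.5 is
the conventional ceiling for a usable reference gene.

Two reporting modes are provided:

* ``single_pass`` — one M per gene computed on the full panel (gives every
  gene a distinct value, the shape of a published ranking table);
* ``stepwise`` — the classical geNorm procedure that repeatedly drops the
  highest-M gene and recomputes, leaving a final most-stable pair.

The pairwise-variation curve V(n/n+1) compares normalization factors
(per-sample geometric means of the top-n genes' quantities) between
consecutive panel sizes; the smallest n with V < 0.15 is the recommended
number of reference genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ranks_ascending, sample_sd
from .cq_data import CqMatrix, InsufficientDataError

__all__ = [
    "RelativeQuantityMatrix",
    "GenormResult",
    "PairwiseVariationCurve",
    "to_relative_quantities",
    "genorm_m_values",
    "genorm_stepwise_ranking",
    "pairwise_variation_curve",
]

M_UPPER_LIMIT = 1.5  # conventional ceiling for a usable reference gene
V_THRESHOLD = 0.15  # pairwise-variation cutoff for adding another gene


@dataclass
class RelativeQuantityMatrix:
    """Relative quantities q in (0, 1], gene x sample; max per gene = 1."""

    q: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.q.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("relative quantities must be finite and positive")

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)


@dataclass
class GenormResult:
    """Per-gene geNorm M value, rank and stability flag."""

    gene: str
    M: float
    rank: int
    mode: str  # "single_pass" or "stepwise"
    stable: bool = True  # False if full-panel M exceeds the 1.5 ceiling


@dataclass
class PairwiseVariationCurve:
    """V(n/n+1) values and the resulting optimal reference-gene count."""

    n: list[int]  # panel sizes n, one per V value (V compares n vs n+1)
    V: list[float]
    threshold: float
    optimal_n: int
    ranking: list[str]  # gene order used to grow the panel

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.V, index=[f"V{n}/{n + 1}" for n in self.n], name="pairwise_variation"
        )


def to_relative_quantities(
    m: CqMatrix, efficiency_percent: dict[str, float] | float | None = None
) -> RelativeQuantityMatrix:
    """Transform Cq to relative quantities q = (1 + E/100)^(Cq_min − Cq).

    ``efficiency_percent`` may be a single value, a per-gene mapping, or
    None for the default 100% (perfect doubling, q = 2^−ΔCq).
    """
    if m.values.isna().any().any():
        raise InsufficientDataError("relative quantities require a complete matrix")
    q = pd.DataFrame(index=m.values.index, columns=m.values.columns, dtype=float)
    for gene in m.values.index:
        if efficiency_percent is None:
            eff = 100.0
        elif isinstance(efficiency_percent, dict):
            eff = float(efficiency_percent.get(gene, 100.0))
        else:
            eff = float(efficiency_percent)
        if eff <= 0:
            raise ValueError(f"{gene}: efficiency must be positive, got {eff}")
        base = 1.0 + eff / 100.0
        cq = m.values.loc[gene].to_numpy(dtype=float)
        q.loc[gene] = base ** (cq.min() - cq)
    return RelativeQuantityMatrix(q=q)


def _m_values(qarr: np.ndarray) -> np.ndarray:
    """M_j = mean over k≠j of SD_s(log2(q_j/q_k)) for a gene x sample array."""
    G = qarr.shape[0]
    logq = np.log2(qarr)
    M = np.zeros(G)
    for j in range(G):
        sds = [float(sample_sd(logq[j] - logq[k])) for k in range(G) if k != j]
        M[j] = float(np.mean(sds))
    return M


def genorm_m_values(q: RelativeQuantityMatrix) -> list[GenormResult]:
    """Single-pass M values on the full panel, ranked ascending."""
    genes = q.genes
    if len(genes) < 3:
        raise InsufficientDataError("geNorm needs >= 3 genes")
    if len(q.samples) < 3:
        raise InsufficientDataError("geNorm needs >= 3 samples")
    M = _m_values(q.q.to_numpy(dtype=float))
    ranks = ranks_ascending(M)
    return [
        GenormResult(
            gene=g,
            M=float(M[i]),
            rank=int(ranks[i]),
            mode="single_pass",
            stable=bool(M[i] <= M_UPPER_LIMIT),
        )
        for i, g in enumerate(genes)
    ]


def genorm_stepwise_ranking(q: RelativeQuantityMatrix) -> list[GenormResult]:
    """Classical geNorm stepwise-exclusion ranking.

    Iteratively recomputes M on the remaining panel and removes the
    highest-M gene (ties: the later gene in input order goes) until two
    remain.  Each excluded gene is reported with its M at exclusion; the
    final two share the top of the ranking (ranks 1 and 2, input order).
    The stability flag still reflects the full-panel M vs the 1.5 ceiling.
    """
    genes = q.genes
    if len(genes) < 3:
        raise InsufficientDataError("geNorm needs >= 3 genes")
    full_M = {g: m for g, m in zip(genes, _m_values(q.q.to_numpy(dtype=float)))}

    remaining = list(genes)
    exclusion_M: dict[str, float] = {}
    order_out: list[str] = []  # worst first
    while len(remaining) > 2:
        arr = q.q.loc[remaining].to_numpy(dtype=float)
        M = _m_values(arr)
        # highest M loses; on ties prefer removing the later gene in input order
        worst_val = M.max()
        worst_idx = max(i for i in range(len(remaining)) if M[i] == worst_val)
        gene = remaining.pop(worst_idx)
        exclusion_M[gene] = float(M[worst_idx])
        order_out.append(gene)

    final_arr = q.q.loc[remaining].to_numpy(dtype=float)
    final_M = _m_values(final_arr)  # the single pair SD, equal for both
    for g, mval in zip(remaining, final_M):
        exclusion_M[g] = float(mval)

    ranking = remaining + order_out[::-1]  # best first
    rank_of = {g: i + 1 for i, g in enumerate(ranking)}
    return [
        GenormResult(
            gene=g,
            M=exclusion_M[g],
            rank=rank_of[g],
            mode="stepwise",
            stable=bool(full_M[g] <= M_UPPER_LIMIT),
        )
        for g in genes
    ]


def pairwise_variation_curve(
    q: RelativeQuantityMatrix,
    ranking: list[str] | None = None,
    threshold: float = V_THRESHOLD,
) -> PairwiseVariationCurve:
    """Pairwise variation V(n/n+1) along a stability ranking.

    NF_n,s is the geometric mean over the top-n ranked genes of q_gs;
    V(n/n+1) is the SD over samples of log2(NF_n/NF_{n+1}).  The optimal
    panel size is the smallest n with V < threshold (all G genes if the
    threshold is never met).
    """
    if ranking is None:
        ranking = [r.gene for r in sorted(genorm_stepwise_ranking(q), key=lambda r: r.rank)]
    if len(ranking) < 3:
        raise InsufficientDataError("pairwise variation needs >= 3 ranked genes")
    missing = [g for g in ranking if g not in q.q.index]
    if missing:
        raise ValueError(f"ranking names unknown genes: {missing}")

    logq = np.log2(q.q.loc[ranking].to_numpy(dtype=float))
    G = len(ranking)
    ns: list[int] = []
    vs: list[float] = []
    for n in range(2, G):
        log_nf_n = logq[:n].mean(axis=0)  # log2 of geometric mean
        log_nf_n1 = logq[: n + 1].mean(axis=0)
        ns.append(n)
        vs.append(float(sample_sd(log_nf_n - log_nf_n1)))

    optimal = next((n for n, v in zip(ns, vs) if v < threshold), G)
    return PairwiseVariationCurve(
        n=ns, V=vs, threshold=threshold, optimal_n=int(optimal), ranking=list(ranking)
    )
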