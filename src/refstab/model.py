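"""Model/results surface for the full stability pipeline.

``ReferenceGeneStability`` bundles a Cq matrix with sample groups; its
``fit()`` runs all four stability algorithms, the consensus aggregation
and the pairwise-variation curve on one shared complete-case submatrix,
returning a ``StabilityResults`` object with per-method tables, a
combined ranking table and a text ``summary()``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cq_data import CqMatrix, complete_case_submatrix
from .consensus_ranking import ConsensusResult, aggregate_rankings
from .stability_bestkeeper import (
    BestkeeperResult,
    CorrelationMatrix,
    bestkeeper_stats,
)
from .stability_deltacq import DeltaCqResult, delta_cq_stability
from .stability_genorm import (
    GenormResult,
    PairwiseVariationCurve,
    genorm_m_values,
    genorm_stepwise_ranking,
    pairwise_variation_curve,
    to_relative_quantities,
)
from .stability_normfinder import NormfinderResult, normfinder_stability

__all__ = ["ReferenceGeneStability", "StabilityResults"]


class ReferenceGeneStability:
    """Reference-gene stability model for one Cq dataset.

    Parameters
    ----------
    cq : CqMatrix
        Replicate-collapsed Cq values with sample metadata (groups).
    genes : sequence of str, optional
        Candidate subset; defaults to every gene in the matrix.

    Examples
    --------
    >>> model = ReferenceGeneStability.from_dataframes(cq_df, meta_df)
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, cq: CqMatrix, genes: Sequence[str] | None = None):
        self.cq_full = cq
        self.genes = list(genes) if genes is not None else cq.genes
        # all four algorithms see the identical complete-case submatrix
        self.cq = complete_case_submatrix(cq, self.genes)

    @classmethod
    def from_dataframes(
        cls,
        values: pd.DataFrame,
        meta: pd.DataFrame | None = None,
        genes: Sequence[str] | None = None,
    ) -> "ReferenceGeneStability":
        """Build from a gene x sample DataFrame and a sample metadata frame
        (indexed by sample, with a ``group`` column)."""
        return cls(CqMatrix(values=values, meta=meta), genes=genes)

    def fit(
        self,
        v_threshold: float = 0.15,
        dispersion_mode: str = "mad",
        efficiency_percent: dict[str, float] | float | None = None,
        grouped: bool | None = None,
    ) -> "StabilityResults":
        """Run ΔCq, geNorm (both modes), NormFinder, BestKeeper, the
        consensus aggregation and the V(n/n+1) curve."""
        if grouped is None:
            grouped = self.cq.meta is not None

        deltacq = delta_cq_stability(self.cq)
        q = to_relative_quantities(self.cq, efficiency_percent)
        genorm_single = genorm_m_values(q)
        genorm_stepwise = genorm_stepwise_ranking(q)
        stepwise_order = [
            r.gene for r in sorted(genorm_stepwise, key=lambda r: r.rank)
        ]
        v_curve = pairwise_variation_curve(q, stepwise_order, threshold=v_threshold)
        normfinder = normfinder_stability(self.cq, grouped=grouped)
        bestkeeper, corr = bestkeeper_stats(self.cq, dispersion_mode=dispersion_mode)

        rankings = {
            "deltacq": {r.gene: float(r.rank) for r in deltacq},
            "genorm": {r.gene: float(r.rank) for r in genorm_single},
            "normfinder": {r.gene: float(r.rank) for r in normfinder},
            "bestkeeper": {r.gene: float(r.rank) for r in bestkeeper},
        }
        consensus = aggregate_rankings(rankings)

        return StabilityResults(
            model=self,
            deltacq=deltacq,
            genorm_single=genorm_single,
            genorm_stepwise=genorm_stepwise,
            pairwise_variation=v_curve,
            normfinder=normfinder,
            bestkeeper=bestkeeper,
            correlations=corr,
            consensus=consensus,
            n_dropped_samples=self.cq.n_dropped_samples,
        )


@dataclass
class StabilityResults:
    """Fitted stability tables for one candidate panel."""

    model: ReferenceGeneStability
    deltacq: list[DeltaCqResult]
    genorm_single: list[GenormResult]
    genorm_stepwise: list[GenormResult]
    pairwise_variation: PairwiseVariationCurve
    normfinder: list[NormfinderResult]
    bestkeeper: list[BestkeeperResult]
    correlations: CorrelationMatrix
    consensus: list[ConsensusResult]
    n_dropped_samples: int = 0

    # -- tabular views ---------------------------------------------------
    def combined_table(self) -> pd.DataFrame:
        """One row per gene: metric + rank for each method, plus consensus."""
        genes = [r.gene for r in self.deltacq]
        by_gene = {
            "deltacq_sd": {r.gene: r.mean_pair_sd for r in self.deltacq},
            "deltacq_rank": {r.gene: r.rank for r in self.deltacq},
            "genorm_M": {r.gene: r.M for r in self.genorm_single},
            "genorm_rank": {r.gene: r.rank for r in self.genorm_single},
            "normfinder_SV": {r.gene: r.SV for r in self.normfinder},
            "normfinder_rank": {r.gene: r.rank for r in self.normfinder},
            "bestkeeper_r": {
                r.gene: (np.nan if r.r_vs_index is None else r.r_vs_index)
                for r in self.bestkeeper
            },
            "bestkeeper_rank": {r.gene: r.rank for r in self.bestkeeper},
            "consensus_geomean": {r.gene: r.geomean_rank for r in self.consensus},
            "consensus_rank": {r.gene: r.final_rank for r in self.consensus},
        }
        df = pd.DataFrame({k: [v[g] for g in genes] for k, v in by_gene.items()})
        df.insert(0, "gene", genes)
        return df.set_index("gene")

    def best_genes(self, n: int | None = None) -> list[str]:
        """Consensus-best genes; defaults to the optimal panel size."""
        if n is None:
            n = self.pairwise_variation.optimal_n
        ordered = sorted(self.consensus, key=lambda r: r.final_rank)
        return [r.gene for r in ordered[:n]]

    def summary(self) -> str:
        """Human-readable combined report."""
        df = self.combined_table()
        pv = self.pairwise_variation
        lines = [
            "Reference-gene stability analysis",
            "=" * 70,
            f"genes: {len(df)}   samples: {len(self.model.cq.samples)}"
            f"   dropped (incomplete): {self.n_dropped_samples}",
            "",
            df.sort_values("consensus_rank").to_string(float_format="%.4f"),
            "",
            "Pairwise variation V(n/n+1): "
            + ", ".join(f"V{n}/{n + 1}={v:.4f}" for n, v in zip(pv.n, pv.V)),
            f"optimal number of reference genes (V < {pv.threshold}): {pv.optimal_n}",
            f"recommended panel: {', '.join(self.best_genes())}",
        ]
        unstable = [r.gene for r in self.genorm_single if not r.stable]
        if unstable:
            lines.append(f"geNorm M > 1.5 (unstable): {', '.join(unstable)}")
        return "\n".join(lines)

    # -- machine surface -------------------------------------------------
    def to_dict(self) -> dict:
        pv = self.pairwise_variation
        return {
            "package_version": __version__,
            "input_hash": _matrix_hash(self.model.cq),
            "n_genes": len(self.model.cq.genes),
            "n_samples": len(self.model.cq.samples),
            "n_dropped_samples": self.n_dropped_samples,
            "deltacq": [
                {"gene": r.gene, "mean_pair_sd": r.mean_pair_sd, "rank": r.rank}
                for r in self.deltacq
            ],
            "genorm_single_pass": [
                {"gene": r.gene, "M": r.M, "rank": r.rank, "stable": r.stable}
                for r in self.genorm_single
            ],
            "genorm_stepwise": [
                {"gene": r.gene, "M": r.M, "rank": r.rank, "stable": r.stable}
                for r in self.genorm_stepwise
            ],
            "pairwise_variation": {
                "n": pv.n,
                "V": pv.V,
                "threshold": pv.threshold,
                "optimal_n": pv.optimal_n,
                "ranking": pv.ranking,
            },
            "normfinder": [
                {"gene": r.gene, "SV": r.SV, "rank": r.rank} for r in self.normfinder
            ],
            "bestkeeper": [
                {
                    "gene": r.gene,
                    "gm_cq": r.gm_cq,
                    "am_cq": r.am_cq,
                    "min_cq": r.min_cq,
                    "max_cq": r.max_cq,
                    "mad_cq": r.mad_cq,
                    "sd_cq": r.sd_cq,
                    "cv_percent": r.cv_percent,
                    "r_vs_index": r.r_vs_index,
                    "p_vs_index": r.p_vs_index,
                    "rank": r.rank,
                    "inconsistent": r.inconsistent,
                }
                for r in self.bestkeeper
            ],
            "consensus": [
                {
                    "gene": r.gene,
                    "method_ranks": r.method_ranks,
                    "geomean_rank": r.geomean_rank,
                    "final_rank": r.final_rank,
                }
                for r in self.consensus
            ],
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _matrix_hash(cq: CqMatrix) -> str:
    payload = cq.values.to_csv().encode()
    return hashlib.sha256(payload).hexdigest()[:16]
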