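"""BestKeeper descriptive stability analysis.

BestKeeper works on raw Cq.  It builds an index — the per-sample geometric
mean of all candidate genes' Cq — and judges each candidate by (a) its own
Cq dispersion and (b) the Pearson correlation of its Cq with the index.
Unlike the ratio-based methods, BestKeeper deliberately keeps the shared
per-sample component: a good reference gene should covary with overall
template amount, so a high r against the index is evidence of stability.

Dispersion defaults to the mean absolute deviation from the arithmetic
mean (the convention of the original tool's "SD (± Cq)" column); the
classical n−1 standard deviation is available as an option, and both are
reported.  Genes with dispersion above 1 cycle are flagged inconsistent
but never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ranks_descending, sample_sd
from .cq_data import CqMatrix, InsufficientDataError

__all__ = [
    "BestkeeperResult",
    "CorrelationMatrix",
    "bestkeeper_index",
    "bestkeeper_stats",
]

INCONSISTENCY_SD = 1.0  # cycles; convention for flagging a noisy candidate


@dataclass
class BestkeeperResult:
    """Per-gene Cq descriptives and correlation with the BestKeeper index."""

    gene: str
    gm_cq: float
    am_cq: float
    min_cq: float
    max_cq: float
    dispersion: float  # the mode chosen for ranking (mad or sd)
    mad_cq: float
    sd_cq: float
    cv_percent: float
    r_vs_index: float | None  # None when the gene has zero variance
    p_vs_index: float | None
    rank: int
    inconsistent: bool = False
    zero_variance: bool = False


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations between candidate genes."""

    genes: list[str]
    r: pd.DataFrame
    p: pd.DataFrame


def bestkeeper_index(m: CqMatrix) -> pd.Series:
    """Per-sample geometric mean of all genes' Cq values."""
    values = m.values
    if values.isna().any().any():
        raise InsufficientDataError("BestKeeper index requires a complete matrix")
    arr = values.to_numpy(dtype=float)
    if np.any(arr <= 0):
        raise ValueError("Cq values must be positive for the geometric mean")
    index = np.exp(np.log(arr).mean(axis=0))
    return pd.Series(index, index=values.columns, name="bestkeeper_index")


def bestkeeper_stats(
    m: CqMatrix, dispersion_mode: str = "mad"
) -> tuple[list[BestkeeperResult], CorrelationMatrix]:
    """Per-gene BestKeeper descriptives, index correlations and ranking.

    Ranks descend by r against the index (ties by input order); genes whose
    Cq vector is constant have undefined r and are ranked last, flagged.
    """
    if dispersion_mode not in ("mad", "sd"):
        raise ValueError("dispersion_mode must be 'mad' or 'sd'")
    values = m.values
    if values.shape[1] < 3:
        raise InsufficientDataError("BestKeeper needs >= 3 samples")
    index = bestkeeper_index(m).to_numpy()
    genes = list(values.index)
    arr = values.to_numpy(dtype=float)

    mads = np.abs(arr - arr.mean(axis=1, keepdims=True)).mean(axis=1)
    sds = sample_sd(arr, axis=1)
    r_list: list[float | None] = []
    p_list: list[float | None] = []
    for i in range(len(genes)):
        if np.ptp(arr[i]) == 0 or np.ptp(index) == 0:
            r_list.append(None)
            p_list.append(None)
        else:
            r, p = stats.pearsonr(arr[i], index)
            r_list.append(float(r))
            p_list.append(float(p))

    # undefined r sorts below any real correlation
    sortable = np.array([r if r is not None else -np.inf for r in r_list])
    ranks = ranks_descending(sortable)

    results = []
    for i, g in enumerate(genes):
        disp = float(mads[i]) if dispersion_mode == "mad" else float(sds[i])
        am = float(arr[i].mean())
        results.append(
            BestkeeperResult(
                gene=g,
                gm_cq=float(np.exp(np.log(arr[i]).mean())),
                am_cq=am,
                min_cq=float(arr[i].min()),
                max_cq=float(arr[i].max()),
                dispersion=disp,
                mad_cq=float(mads[i]),
                sd_cq=float(sds[i]),
                cv_percent=float(disp / am * 100.0),
                r_vs_index=r_list[i],
                p_vs_index=p_list[i],
                rank=int(ranks[i]),
                inconsistent=bool(disp > INCONSISTENCY_SD),
                zero_variance=r_list[i] is None,
            )
        )

    G = len(genes)
    rmat = np.eye(G)
    pmat = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            if np.ptp(arr[i]) == 0 or np.ptp(arr[j]) == 0:
                rmat[i, j] = rmat[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
            else:
                r, p = stats.pearsonr(arr[i], arr[j])
                rmat[i, j] = rmat[j, i] = float(r)
                pmat[i, j] = pmat[j, i] = float(p)
    corr = CorrelationMatrix(
        genes=genes,
        r=pd.DataFrame(rmat, index=genes, columns=genes),
        p=pd.DataFrame(pmat, index=genes, columns=genes),
    )
    return results, corr
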