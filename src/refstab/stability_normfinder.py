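"""NormFinder model-based reference-gene stability.

NormFinder treats log-scale expression of gene i in sample j of group g as

    x_igj = alpha_i + beta_g + d_ig + eps_igj,

where d_ig is the gene x group interaction (systematic regulation across
groups — the worst property a reference gene can have) and eps has
gene x group variance sigma²_ig.  Both components are estimated from the
sample-centered data and combined into one stability value

    SV_i = (1/K) * sum_g ( |d~_ig| + sqrt(sigmâ²_ig / n_g) ),

where d~ is the intergroup deviation shrunk toward zero in proportion to
its sampling noise.  Lower SV = more stable.

All steps operate on sample-centered data and are therefore exactly
invariant to per-sample loading shifts and to per-gene constant offsets;
we run directly on x = −Cq (log2 expression up to a per-gene constant),
which is equivalent to any 2^±ΔCq relative-quantity transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ranks_ascending
from .cq_data import CqMatrix, InsufficientDataError

__all__ = ["NormfinderResult", "normfinder_stability"]


@dataclass
class NormfinderResult:
    """Per-gene NormFinder stability value and variance components."""

    gene: str
    SV: float
    rank: int
    intragroup_var: dict[str, float] = field(default_factory=dict)
    #: raw centered gene x group deviations d_ig (sum to 0 within a group)
    intergroup_dev: dict[str, float] = field(default_factory=dict)
    #: deviations after shrinkage toward 0; these enter the SV
    intergroup_dev_shrunk: dict[str, float] = field(default_factory=dict)


def normfinder_stability(
    m: CqMatrix, grouped: bool = True
) -> list[NormfinderResult]:
    """Compute NormFinder stability values for every gene.

    With ``grouped=True`` the sample groups come from the matrix metadata
    and both variance components are estimated (every group needs >= 2
    samples).  With ``grouped=False`` (or a single group) only the residual
    variance is estimated and SV_i = sqrt(sigmâ²_i).

    Requires >= 3 genes: the intragroup variance correction removes the
    contribution of the shared sample centering, which is only identified
    for G >= 3.
    """
    values = m.values
    if values.isna().any().any():
        raise InsufficientDataError("NormFinder requires a complete matrix")
    genes = list(values.index)
    G = len(genes)
    if G < 3:
        raise InsufficientDataError("NormFinder needs >= 3 genes")

    x = -values.to_numpy(dtype=float)  # log2 expression up to per-gene constant

    if grouped and m.meta is not None:
        group_labels = m.groups().to_numpy()
        group_names = list(dict.fromkeys(group_labels))  # stable order
    else:
        group_labels = np.array(["all"] * x.shape[1])
        group_names = ["all"]
    K = len(group_names)

    if K > 1:
        counts = {g: int((group_labels == g).sum()) for g in group_names}
        thin = [g for g, n in counts.items() if n < 2]
        if thin:
            raise InsufficientDataError(
                f"groups with fewer than 2 samples: {thin}"
            )

    # (1) sample-center: remove per-sample mean over genes (loading + any
    # shared group effect)
    z = x - x.mean(axis=0, keepdims=True)

    # (2) per gene x group means and variances
    d_hat = np.zeros((G, K))
    s2 = np.zeros((G, K))
    n_g = np.zeros(K, dtype=int)
    for k, gname in enumerate(group_names):
        cols = group_labels == gname
        n_g[k] = int(cols.sum())
        zg = z[:, cols]
        d_hat[:, k] = zg.mean(axis=1)
        s2[:, k] = zg.var(axis=1, ddof=1) if n_g[k] > 1 else 0.0
    # the interaction deviations: remove each gene's own baseline (mean over
    # groups) and re-center across genes within each group; after both, rows
    # and columns of d_hat sum to zero (two-way interaction residual)
    d_hat -= d_hat.mean(axis=1, keepdims=True)
    d_hat -= d_hat.mean(axis=0, keepdims=True)

    # (3) intragroup variance, corrected for the shared centering term
    sigma2 = np.zeros((G, K))
    for k in range(K):
        total = s2[:, k].sum() / (G**2 * (1.0 - 1.0 / G))
        sigma2[:, k] = np.maximum(0.0, (s2[:, k] - total) / (1.0 - 2.0 / G))

    if K == 1:
        sv = np.sqrt(sigma2[:, 0])
        ranks = ranks_ascending(sv)
        return [
            NormfinderResult(
                gene=g,
                SV=float(sv[i]),
                rank=int(ranks[i]),
                intragroup_var={"all": float(sigma2[i, 0])},
                intergroup_dev={"all": 0.0},
                intergroup_dev_shrunk={"all": 0.0},
            )
            for i, g in enumerate(genes)
        ]

    # (4) common intergroup variance gamma², method-of-moments with floor
    gamma2 = max(
        0.0,
        (d_hat**2).sum() / ((G - 1) * (K - 1))
        - (sigma2 / n_g[None, :]).sum() / (G * K),
    )

    # (5) shrink the observed deviations toward 0 by their sampling noise
    with np.errstate(invalid="ignore"):
        shrink = (
            gamma2 / (gamma2 + sigma2 / n_g[None, :])
            if gamma2 > 0
            else np.zeros((G, K))
        )
    d_tilde = d_hat * shrink

    # (6) combine into one stability value per gene
    sv = (np.abs(d_tilde) + np.sqrt(sigma2 / n_g[None, :])).mean(axis=1)
    ranks = ranks_ascending(sv)
    return [
        NormfinderResult(
            gene=g,
            SV=float(sv[i]),
            rank=int(ranks[i]),
            intragroup_var={gr: float(sigma2[i, k]) for k, gr in enumerate(group_names)},
            intergroup_dev={gr: float(d_hat[i, k]) for k, gr in enumerate(group_names)},
            intergroup_dev_shrunk={
                gr: float(d_tilde[i, k]) for k, gr in enumerate(group_names)
            },
        )
        for i, g in enumerate(genes)
    ]
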