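"""Relative expression by the 2^−ΔΔCq method, with multi-gene references
and between-run correction.

ΔCq_s = Cq_target,s − Cq_ref,s normalizes each sample to its reference
signal; subtracting the calibrator's ΔCq and exponentiating gives the fold
change 2^−ΔΔCq (unit fold at the calibrator).  Multi-gene references are
aggregated by mean Cq, which equals the log2 of the geometric mean of
their quantities.  The Livak form assumes ~100% amplification efficiency;
an efficiency-corrected variant using per-gene (1 + E)^Cq quantities is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq_data import CqMatrix, CqValidationError

__all__ = [
    "RelExprTable",
    "RunCorrection",
    "reference_cq",
    "ddcq_fold_change",
    "between_run_correction",
]


@dataclass
class RelExprTable:
    """Per-sample fold changes for one target relative to a calibrator."""

    target: str
    reference_genes: list[str]
    calibrator: str  # sample id or group label
    table: pd.DataFrame  # columns: sample, group, fold_change


@dataclass
class RunCorrection:
    plate: str
    factor: float


def reference_cq(m: CqMatrix, reference_genes: list[str]) -> pd.Series:
    """Per-sample mean Cq over the reference genes.

    The arithmetic mean of Cq equals log2 of the geometric mean of the
    genes' relative quantities, the recommended multi-gene aggregation.
    """
    if not reference_genes:
        raise CqValidationError("reference gene set is empty")
    missing = [g for g in reference_genes if g not in m.values.index]
    if missing:
        raise CqValidationError(f"reference genes not in matrix: {missing}")
    sub = m.values.loc[reference_genes]
    if sub.isna().any().any():
        raise CqValidationError("reference genes have missing Cq values")
    return sub.mean(axis=0)


def ddcq_fold_change(
    target_cq: pd.Series,
    ref_cq: pd.Series,
    calibrator: str,
    groups: pd.Series | None = None,
    target: str = "target",
    reference_genes: list[str] | None = None,
    efficiency_percent: float | None = None,
    calibrator_delta_cq: float | None = None,
) -> RelExprTable:
    """Fold changes fold_s = B^−[(ΔCq_s) − ΔCq_cal], B = 1 + E/100 (default 2).

    ``calibrator`` is a sample id, or a group label when ``groups`` is
    given (the calibrator ΔCq is then the mean over that group's samples).
    ``calibrator_delta_cq`` overrides the calibrator lookup with an
    explicit baseline ΔCq — the shared-calibrator mode used when several
    targets are scaled to one target's baseline group.
    """
    target_cq = target_cq.astype(float)
    ref_cq = ref_cq.reindex(target_cq.index).astype(float)
    if ref_cq.isna().any():
        raise CqValidationError("reference Cq missing for some samples")
    delta = target_cq - ref_cq

    if calibrator_delta_cq is not None:
        cal_delta = float(calibrator_delta_cq)
    elif groups is not None and (groups == calibrator).any():
        cal_delta = float(delta[groups.reindex(delta.index) == calibrator].mean())
    elif calibrator in delta.index:
        cal_delta = float(delta[calibrator])
    else:
        raise CqValidationError(f"calibrator {calibrator!r} not found")

    base = 2.0 if efficiency_percent is None else 1.0 + efficiency_percent / 100.0
    if base <= 1.0:
        raise ValueError("efficiency must be positive")
    fold = base ** (-(delta - cal_delta))

    table = pd.DataFrame(
        {
            "sample": delta.index,
            "group": (
                groups.reindex(delta.index).to_numpy()
                if groups is not None
                else delta.index
            ),
            "fold_change": fold.to_numpy(),
        }
    )
    return RelExprTable(
        target=target,
        reference_genes=list(reference_genes or []),
        calibrator=calibrator,
        table=table,
    )


def between_run_correction(
    quantities: pd.Series,
    plates: pd.Series,
    calibrator_samples: list[str],
) -> tuple[list[RunCorrection], pd.Series]:
    """Remove between-plate scale shifts using shared calibrator samples.

    Each plate's factor is the geometric mean of its calibrator
    quantities divided by the overall geometric mean; factors are then
    renormalized to unit geometric mean and each quantity divided by its
    plate's factor.  Every plate must carry at least one calibrator
    sample; calibrators re-measured on several plates may appear as
    repeated index labels with different plate labels.
    """
    if not calibrator_samples:
        raise CqValidationError("no calibrator samples given")
    plates = plates.reindex(quantities.index)
    if plates.isna().any():
        raise CqValidationError("every quantity needs a plate label")
    if (quantities <= 0).any():
        raise ValueError("quantities must be positive")

    plate_names = list(dict.fromkeys(plates))
    log_gm: dict[str, float] = {}
    for p in plate_names:
        on_plate = quantities[(plates == p) & quantities.index.isin(calibrator_samples)]
        if on_plate.empty:
            raise CqValidationError(f"plate {p!r} is missing calibrator samples")
        log_gm[p] = float(np.log(on_plate).mean())

    overall = float(np.mean(list(log_gm.values())))
    log_factors = {p: lg - overall for p, lg in log_gm.items()}
    # renormalize to unit geometric mean over plates (already centered, but
    # enforce against float drift)
    center = float(np.mean(list(log_factors.values())))
    factors = {p: float(np.exp(lf - center)) for p, lf in log_factors.items()}

    corrected = quantities / plates.map(factors).astype(float)
    runs = [RunCorrection(plate=p, factor=factors[p]) for p in plate_names]
    return runs, corrected
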