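"""Dilution-series standard curves and amplification efficiency.

A standard curve regresses Cq against log10 of the template amount over a
serial dilution.  For a perfectly doubling assay the slope is
-1/log10(2) = -3.3219 cycles per tenfold dilution; the per-cycle
amplification efficiency follows as E% = (10^(-1/slope) - 1) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurveFit",
    "StandardCurve",
    "fit_standard_curve",
    "efficiency_from_slope",
]


@dataclass
class DilutionSeries:
    """Cq measurements of one assay over a dilution series.

    ``cq`` holds, per dilution level, the replicate Cq values (NaN allowed
    for failed wells).  ``relative_amounts`` must be monotone so the series
    is a genuine dilution (or concentration) ladder.
    """

    gene: str
    relative_amounts: np.ndarray
    cq: list[np.ndarray]  # one array of replicate Cq per level

    def __post_init__(self) -> None:
        self.relative_amounts = np.asarray(self.relative_amounts, dtype=float)
        self.cq = [np.atleast_1d(np.asarray(c, dtype=float)) for c in self.cq]
        if len(self.relative_amounts) != len(self.cq):
            raise ValueError("one Cq replicate set required per dilution level")
        if len(self.relative_amounts) < 3:
            raise ValueError("need >= 3 dilution levels")
        if np.any(self.relative_amounts <= 0):
            raise ValueError("relative amounts must be positive")
        diffs = np.diff(self.relative_amounts)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("relative amounts must be strictly monotone")


@dataclass
class StandardCurveFit:
    """OLS fit of mean Cq per level on log10(relative amount)."""

    gene: str
    slope: float  # cycles per log10-dilution
    intercept: float  # cycles at relative amount 1
    r_squared: float
    efficiency_percent: float
    n_levels: int
    positive_slope_warning: bool = False

    def summary(self) -> str:
        lines = [
            f"Standard curve: {self.gene}",
            f"  slope       {self.slope: .4f} cycles / log10",
            f"  intercept   {self.intercept: .4f} cycles",
            f"  R^2         {self.r_squared: .4f}",
            f"  efficiency  {self.efficiency_percent: .2f} %",
        ]
        if self.positive_slope_warning:
            lines.append("  WARNING: positive slope; assay not physically meaningful")
        return "\n".join(lines)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent, E% = (10^(-1/slope) - 1) * 100."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(series: DilutionSeries, pooled: bool = False) -> StandardCurveFit:
    """Fit one assay's standard curve.

    By default the replicate Cq values are averaged per dilution level and
    the level means are regressed on log10(amount); ``pooled=True`` instead
    regresses every replicate well individually.
    """
    x_parts: list[float] = []
    y_parts: list[float] = []
    for amount, reps in zip(series.relative_amounts, series.cq):
        good = reps[np.isfinite(reps)]
        if good.size == 0:
            continue
        if pooled:
            x_parts.extend([np.log10(amount)] * good.size)
            y_parts.extend(good.tolist())
        else:
            x_parts.append(np.log10(amount))
            y_parts.append(float(np.mean(good)))
    x = np.asarray(x_parts)
    y = np.asarray(y_parts)
    if np.unique(x).size < 2:
        raise ValueError(
            f"{series.gene}: all usable points at one dilution level; cannot fit"
        )
    if np.unique(x).size < 3:
        raise ValueError(f"{series.gene}: need >= 3 usable dilution levels")

    res = stats.linregress(x, y)
    slope = float(res.slope)
    return StandardCurveFit(
        gene=series.gene,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency_percent=efficiency_from_slope(slope),
        n_levels=int(np.unique(x).size),
        positive_slope_warning=slope > 0,
    )


class StandardCurve:
    """Model-style wrapper: ``StandardCurve(series).fit()`` -> fit results."""

    def __init__(self, series: DilutionSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df, gene: str | None = None) -> "StandardCurve":
        """Build from a long table with columns gene, relative_amount, Cq."""
        if gene is not None:
            df = df[df["gene"] == gene]
        if df.empty:
            raise ValueError("no rows for requested gene")
        name = str(df["gene"].iloc[0])
        levels = sorted(df["relative_amount"].unique())
        cq = [df.loc[df["relative_amount"] == lv, "Cq"].to_numpy(float) for lv in levels]
        return cls(DilutionSeries(gene=name, relative_amounts=np.array(levels), cq=cq))

    def fit(self, pooled: bool = False) -> StandardCurveFit:
        return fit_standard_curve(self.series, pooled=pooled)
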