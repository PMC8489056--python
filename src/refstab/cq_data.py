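"""Data model and I/O for quantification-cycle (Cq) datasets.

A Cq dataset enters as raw per-well records (one technical replicate per
row), is collapsed to one value per gene x biological sample, and is then
shared by every downstream stability and quantification routine.  Missing
Cq (no amplification, "Undetermined") is carried explicitly and never
imputed: each algorithm runs on its complete-case submatrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawCqRecord",
    "CqMatrix",
    "CqParseError",
    "CqValidationError",
    "InsufficientDataError",
    "read_cq_table",
    "read_sample_meta",
    "collapse_replicates",
    "complete_case_submatrix",
]

#: cell texts treated as "no amplification"
MISSING_SENTINELS = {"", "undetermined", "na", "nan", "n/a", "none", "null"}

DEFAULT_OUTLIER_RANGE = 0.5  # cycles; replicate spread above this is flagged


class CqParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


class CqValidationError(ValueError):
    """Structural problem: duplicated keys, unknown samples, bad metadata."""


class InsufficientDataError(ValueError):
    """Too few samples (or genes) survive for the requested computation."""


@dataclass(frozen=True)
class RawCqRecord:
    """One technical-replicate qPCR well."""

    sample_id: str
    gene: str
    technical_rep: int
    Cq: float | None  # cycles; None = no amplification
    plate: str = "plate1"

    def __post_init__(self) -> None:
        if self.technical_rep < 1:
            raise CqValidationError(
                f"technical_rep must be >= 1, got {self.technical_rep}"
            )
        if self.Cq is not None and (not math.isfinite(self.Cq) or self.Cq <= 0):
            raise CqValidationError(
                f"Cq must be finite and > 0 when present, got {self.Cq!r} "
                f"({self.sample_id}/{self.gene}/rep{self.technical_rep})"
            )


@dataclass
class CqMatrix:
    """Technical-replicate-collapsed Cq values, gene x sample.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows = genes, columns = sample ids, entries = mean Cq in cycles
        (NaN marks missing cells).
    meta : pandas.DataFrame
        Indexed by sample id with columns ``group`` and ``biological_rep``.
    rep_flags : pandas.DataFrame
        Boolean, same shape as ``values``; True where the technical
        replicates spread more than the configured outlier range.
    plates : pandas.Series
        Plate label per sample (first plate seen for that sample).
    """

    values: pd.DataFrame
    meta: pd.DataFrame | None = None
    rep_flags: pd.DataFrame | None = None
    plates: pd.Series | None = None
    n_dropped_samples: int = 0

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise CqValidationError("duplicated gene labels")
        if self.values.columns.duplicated().any():
            raise CqValidationError("duplicated sample labels")
        if self.rep_flags is None:
            self.rep_flags = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.meta is not None:
            missing = set(self.values.columns) - set(self.meta.index)
            if missing:
                raise CqValidationError(
                    f"samples without metadata: {sorted(missing)}"
                )

    # -- convenience -----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> pd.Series:
        """Group label per sample; requires metadata."""
        if self.meta is None:
            raise CqValidationError("CqMatrix has no sample metadata")
        return self.meta.loc[self.values.columns, "group"]

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    # -- round-trip I/O --------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, meta: pd.DataFrame | None = None) -> "CqMatrix":
        values = pd.read_csv(path, index_col="gene", float_precision="round_trip")
        return cls(values=values, meta=meta)


# ---------------------------------------------------------------------------
# parsing


def _parse_cq_cell(raw, row_no: int, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in MISSING_SENTINELS:
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise CqParseError(
            f"row {row_no}, column {column!r}: cannot parse Cq value {raw!r}"
        ) from exc
    if not math.isfinite(value):
        return None
    return value


def read_cq_table(path, layout: str = "long") -> list[RawCqRecord]:
    """Read raw per-replicate Cq records from CSV.

    ``layout="long"`` expects columns ``sample,gene,rep,plate,Cq`` (``rep``
    and ``plate`` optional, defaulting to 1 / "plate1").  ``layout="wide"``
    expects a first column ``sample`` and one column per gene; repeated
    sample rows are numbered as successive technical replicates.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]

    records: list[RawCqRecord] = []
    if layout == "long":
        required = {"sample", "gene", "Cq"}
        if not required.issubset(df.columns):
            raise CqValidationError(
                f"long layout requires columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        for i, row in df.iterrows():
            rep = int(row["rep"]) if "rep" in df.columns and not pd.isna(row["rep"]) else 1
            plate = (
                str(row["plate"])
                if "plate" in df.columns and not pd.isna(row["plate"])
                else "plate1"
            )
            records.append(
                RawCqRecord(
                    sample_id=str(row["sample"]),
                    gene=str(row["gene"]),
                    technical_rep=rep,
                    plate=plate,
                    Cq=_parse_cq_cell(row["Cq"], i + 2, "Cq"),
                )
            )
    else:
        if df.columns[0] != "sample":
            raise CqValidationError("wide layout requires first column 'sample'")
        genes = list(df.columns[1:])
        rep_counter: dict[str, int] = {}
        for i, row in df.iterrows():
            sample = str(row["sample"])
            rep_counter[sample] = rep_counter.get(sample, 0) + 1
            for gene in genes:
                records.append(
                    RawCqRecord(
                        sample_id=sample,
                        gene=gene,
                        technical_rep=rep_counter[sample],
                        Cq=_parse_cq_cell(row[gene], i + 2, gene),
                    )
                )

    keys = [(r.sample_id, r.gene, r.technical_rep) for r in records]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise CqValidationError(
            f"duplicate (sample, gene, rep) combinations: {dupes[:5]}"
        )
    return records


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample metadata CSV with columns ``sample,group,biological_rep``."""
    meta = pd.read_csv(path, dtype={"sample": str, "group": str})
    required = {"sample", "group"}
    if not required.issubset(meta.columns):
        raise CqValidationError(
            f"metadata requires columns {sorted(required)}, got {list(meta.columns)}"
        )
    if meta["sample"].duplicated().any():
        raise CqValidationError("duplicated sample ids in metadata")
    if "biological_rep" not in meta.columns:
        meta["biological_rep"] = (
            meta.groupby("group").cumcount() + 1
        )
    return meta.set_index("sample")


# ---------------------------------------------------------------------------
# replicate collapse and complete cases


def collapse_replicates(
    records: Iterable[RawCqRecord],
    outlier_range: float = DEFAULT_OUTLIER_RANGE,
    meta: pd.DataFrame | None = None,
) -> CqMatrix:
    """Collapse technical replicates to one mean Cq per gene x sample.

    The mean is the arithmetic mean of the non-missing replicate Cq values
    (Cq is already log-scale, so this is the natural average).  Cells whose
    replicate range exceeds ``outlier_range`` cycles are flagged but kept;
    cells with no surviving replicate are missing.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("no records to collapse")

    genes: list[str] = []
    samples: list[str] = []
    cells: dict[tuple[str, str], list[float]] = {}
    plates: dict[str, str] = {}
    for r in records:
        if r.gene not in genes:
            genes.append(r.gene)
        if r.sample_id not in samples:
            samples.append(r.sample_id)
            plates[r.sample_id] = r.plate
        if r.Cq is not None:
            cells.setdefault((r.gene, r.sample_id), []).append(r.Cq)

    values = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)
    flags = pd.DataFrame(False, index=genes, columns=samples)
    for (gene, sample), reps in cells.items():
        values.loc[gene, sample] = float(np.mean(reps))
        if len(reps) > 1 and (max(reps) - min(reps)) > outlier_range:
            flags.loc[gene, sample] = True

    return CqMatrix(
        values=values,
        meta=meta,
        rep_flags=flags,
        plates=pd.Series(plates, name="plate"),
    )


def complete_case_submatrix(
    m: CqMatrix, genes: Sequence[str] | None = None, min_samples: int = 3
) -> CqMatrix:
    """Restrict to samples with no missing value in any requested gene."""
    genes = list(genes) if genes is not None else m.genes
    unknown = [g for g in genes if g not in m.values.index]
    if unknown:
        raise CqValidationError(f"unknown genes: {unknown}")

    sub = m.values.loc[genes]
    keep = sub.columns[~sub.isna().any(axis=0)]
    dropped = sub.shape[1] - len(keep)
    if len(keep) < min_samples:
        raise InsufficientDataError(
            f"only {len(keep)} complete samples for genes {genes}; "
            f"need at least {min_samples}"
        )
    return CqMatrix(
        values=sub[keep].copy(),
        meta=m.meta.loc[keep].copy() if m.meta is not None else None,
        rep_flags=m.rep_flags.loc[genes, keep].copy() if m.rep_flags is not None else None,
        plates=m.plates.loc[keep].copy() if m.plates is not None else None,
        n_dropped_samples=dropped,
    )
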