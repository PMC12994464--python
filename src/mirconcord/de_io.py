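"""Reading, validation and thresholding of differential-expression summary tables.

A DE summary table is the tab- or comma-separated file emitted by standard
DE software: one row per feature with a log2 fold-change, a raw p-value and
a multiplicity-adjusted p-value.  This module parses those files into
:class:`DETable`, applies the Benjamini–Hochberg step-up adjustment, and
turns thresholds into per-feature significance/direction calls used by every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

#: canonical column names used internally
COLUMNS = ("feature_id", "log2FoldChange", "pvalue", "padj")

DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "feature_id": "feature_id",
    "log2FoldChange": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
}


class DETableError(ValueError):
    """Raised for malformed DE tables (missing columns, duplicate ids...)."""


@dataclass
class DETable:
    """A single differential-expression contrast.

    ``df`` always carries the canonical columns ``feature_id``,
    ``log2FoldChange``, ``pvalue``, ``padj`` plus a boolean ``tested``
    column (False for rows whose p-value was missing in the source).
    After :func:`call_significant` it additionally carries ``significant``
    (bool) and ``direction`` (``up``/``down``/``none``).
    """

    contrast_id: str
    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise DETableError(f"DE table missing columns: {missing}")
        dup = self.df["feature_id"][self.df["feature_id"].duplicated()]
        if len(dup):
            raise DETableError(
                f"duplicate feature ids in contrast {self.contrast_id!r}: "
                f"{sorted(set(dup))[:5]}"
            )
        if "tested" not in self.df.columns:
            self.df = self.df.assign(tested=self.df["pvalue"].notna())
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_ids(self) -> pd.Series:
        return self.df["feature_id"]

    def record(self, feature_id: str) -> pd.Series:
        rows = self.df[self.df["feature_id"] == feature_id]
        if rows.empty:
            raise KeyError(feature_id)
        return rows.iloc[0]


def _sniff_delimiter(path: Path) -> str:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_de_table(
    path: str | Path,
    contrast_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> DETable:
    """Read a DE summary table from a delimited text file.

    Parameters
    ----------
    path:
        Tab- or comma-separated file with a header row; ``.gz`` transparent.
    column_map:
        Maps canonical names (``feature_id``, ``log2FoldChange``, ``pvalue``,
        ``padj``) to the file's column names.  Omitted entries default to the
        canonical name itself; a missing ``feature_id`` column falls back to
        the file's first column.
    delimiter:
        Force a delimiter instead of auto-detecting among tab/comma.

    Rows with missing p-values are retained but flagged ``tested=False``.
    Duplicate feature ids raise :class:`DETableError` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if cmap["feature_id"] not in raw.columns:
        cmap["feature_id"] = raw.columns[0]
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise DETableError(f"{path}: missing columns {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in cmap.items()})
    df["feature_id"] = df["feature_id"].astype(str)
    for col in ("log2FoldChange", "pvalue", "padj"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = df["pvalue"].dropna()
    if ((bad <= 0) | (bad > 1)).any():
        raise DETableError(f"{path}: p-values outside (0, 1]")
    return DETable(
        contrast_id=contrast_id or path.stem,
        df=df,
        provenance={"path": str(path), "column_map": dict(cmap), "delimiter": sep},
    )


def write_de_table(table: DETable, path: str | Path) -> None:
    """Write the canonical columns as TSV (the format read_de_table expects)."""
    table.df[list(COLUMNS)].to_csv(path, sep="\t", index=False)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q(i) = min_{j >= i} p(j)·n/j over the ascending-sorted p-values, capped
    at 1 and mapped back to the original order; elementwise q >= p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    table: DETable,
    lfc_threshold: float = 0.5,
    padj_threshold: float = 0.05,
    padj_inclusive: bool = False,
) -> DETable:
    """Attach significance and direction calls to a DE table.

    A feature is significant iff ``|log2FoldChange| >= lfc_threshold`` and
    ``padj < padj_threshold`` (``<=`` when ``padj_inclusive``).  Untested
    rows are never significant.  Direction is the sign of the fold-change
    for significant features, ``none`` otherwise.
    """
    if lfc_threshold < 0 or not (0 < padj_threshold <= 1):
        raise ValueError("thresholds must be positive (padj in (0, 1])")
    df = table.df.copy()
    padj = df["padj"].to_numpy(dtype=float)
    lfc = df["log2FoldChange"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        pass_padj = padj <= padj_threshold if padj_inclusive else padj < padj_threshold
        sig = (
            df["tested"].to_numpy(dtype=bool)
            & ~np.isnan(padj)
            & pass_padj
            & (np.abs(lfc) >= lfc_threshold)
        )
    direction = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "none"))
    df["significant"] = sig
    df["direction"] = direction
    return DETable(table.contrast_id, df, dict(table.provenance))


def filter_min_count(
    count_table: pd.DataFrame, min_count: int
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features whose total count is below ``min_count`` (strict).

    ``count_table`` is indexed by feature id with one column per sample.
    Returns the surviving table and the list of removed feature ids.
    """
    counts = count_table.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or (counts < 0).any():
        raise ValueError("counts must be non-negative numbers")
    totals = count_table.sum(axis=1)
    keep = totals >= min_count
    removed = list(count_table.index[~keep].astype(str))
    return count_table.loc[keep], removed
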