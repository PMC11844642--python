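"""Annotated cycle-threshold (CT) tables: reading, validation, reshaping.

A CT table is the unit of analysis for qPCR experiments: one row per
biological sample (optionally per technical replicate), one CT value per
gene, plus two sample annotations — the subject (donor) the sample came
from and the treatment it received.

Missing CT cells are represented as NaN (an explicit missing flag), never
as sentinel values such as 0 or 40; downstream analyses drop samples with
missing required cells and log the count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("qpcrmlm")

LONG_COLUMNS = ("sample", "subject", "treatment", "gene", "ct")
WIDE_ID_COLUMNS = ("sample", "subject", "treatment")
REPLICATE_COLUMN = "replicate"


class QPCRError(Exception):
    """Base class for all qpcrmlm errors."""


class SchemaError(QPCRError):
    """Input file does not match the declared layout."""


class CTParseError(QPCRError):
    """A CT cell could not be parsed as a number."""


class DuplicateRecordError(QPCRError):
    """Duplicate (sample, gene, replicate) record."""


class GeneLookupError(QPCRError, KeyError):
    """A requested gene is not present in the table."""


def _validate_long(data: pd.DataFrame) -> None:
    ct = data["ct"]
    bad = ct.notna() & (~np.isfinite(ct) | (ct < 0))
    if bad.any():
        rows = data.index[bad].tolist()[:5]
        raise CTParseError(
            f"CT values must be finite and non-negative; offending rows: {rows}"
        )
    dup = data.duplicated(subset=["sample", "gene", REPLICATE_COLUMN])
    if dup.any():
        keys = data.loc[dup, ["sample", "gene", REPLICATE_COLUMN]].values.tolist()[:5]
        raise DuplicateRecordError(
            f"duplicate (sample, gene, replicate) records: {keys}"
        )
    ann = data[["sample", "subject", "treatment"]].drop_duplicates()
    dup_ann = ann.duplicated(subset="sample")
    if dup_ann.any():
        samples = ann.loc[dup_ann, "sample"].tolist()
        raise SchemaError(
            f"samples annotated inconsistently (conflicting subject/treatment): {samples}"
        )


@dataclass
class CTTable:
    """Long-format container of per-sample, per-gene CT values.

    ``data`` columns: sample, subject, treatment, gene, ct, replicate.
    Sample and gene order follow first appearance. A NaN ct is a missing
    cell.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if REPLICATE_COLUMN not in df.columns:
            df[REPLICATE_COLUMN] = 1
        df[REPLICATE_COLUMN] = df[REPLICATE_COLUMN].fillna(1).astype(int)
        if (df[REPLICATE_COLUMN] < 1).any():
            raise SchemaError("replicate indices must be >= 1")
        df["ct"] = pd.to_numeric(df["ct"], errors="raise").astype(float)
        for col in ("sample", "subject", "treatment", "gene"):
            df[col] = df[col].astype(str)
        _validate_long(df)
        self.data = df.reset_index(drop=True)

    # -- structure -------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def annotations(self) -> pd.DataFrame:
        """Per-sample annotation frame (index sample, columns subject, treatment)."""
        ann = (
            self.data[["sample", "subject", "treatment"]]
            .drop_duplicates()
            .set_index("sample")
        )
        return ann.loc[self.samples]

    @property
    def treatment_levels(self) -> list[str]:
        return sorted(self.annotations["treatment"].unique())

    @property
    def has_replicates(self) -> bool:
        return bool(self.data.duplicated(subset=["sample", "gene"]).any())

    def wide(self) -> pd.DataFrame:
        """Samples x genes CT matrix (NaN = missing). Requires collapsed data."""
        if self.has_replicates:
            raise SchemaError(
                "table contains technical replicates; collapse_replicates() first"
            )
        mat = self.data.pivot(index="sample", columns="gene", values="ct")
        return mat.reindex(index=self.samples, columns=self.genes)

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.genes:
            raise GeneLookupError(
                f"gene {gene!r} not in table (available: {self.genes})"
            )
        return self.wide()[gene]

    # -- operations ------------------------------------------------------
    def collapse_replicates(self, statistic: str = "mean") -> "CTTable":
        """Collapse technical replicates to one CT per (sample, gene).

        ``statistic`` is ``"mean"`` (default) or ``"median"``. Cells whose
        replicates are all missing stay missing (a warning is logged).
        """
        if statistic not in ("mean", "median"):
            raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
        agg = getattr(np, f"nan{statistic}")
        grouped = (
            self.data.groupby(["sample", "subject", "treatment", "gene"], sort=False)[
                "ct"
            ]
            .apply(lambda v: agg(v) if v.notna().any() else np.nan)
            .reset_index()
        )
        n_missing = int(grouped["ct"].isna().sum())
        if n_missing:
            logger.warning(
                "collapse_replicates: %d (sample, gene) cells have no finite replicate",
                n_missing,
            )
        grouped[REPLICATE_COLUMN] = 1
        return CTTable(grouped)

    def equals(self, other: "CTTable") -> bool:
        a = self.data.sort_values(["sample", "gene", REPLICATE_COLUMN]).reset_index(drop=True)
        b = other.data.sort_values(["sample", "gene", REPLICATE_COLUMN]).reset_index(drop=True)
        return a[list(LONG_COLUMNS) + [REPLICATE_COLUMN]].equals(
            b[list(LONG_COLUMNS) + [REPLICATE_COLUMN]]
        )


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty or headerless file: {path}") from exc
    df.columns = [c.strip() for c in df.columns]
    return df


def _parse_ct_column(raw: pd.Series, label: str) -> pd.Series:
    out = pd.to_numeric(raw.str.strip().replace("", np.nan) if raw.dtype == object else raw,
                        errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # header line is row 1
        raise CTParseError(
            f"non-numeric CT value {raw[bad.idxmax()]!r} in column {label!r} at line {row}"
        )
    return out


def read_ct_table(path, layout: str = "wide") -> CTTable:
    """Read a CT table from CSV.

    ``layout="long"`` expects columns sample, subject, treatment, gene, ct
    (optional replicate); ``layout="wide"`` expects sample, subject,
    treatment plus one column per gene. Empty CT fields become missing
    cells.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = _read_csv(path)
    if layout == "long":
        required = list(LONG_COLUMNS)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"long layout missing column(s): {missing}")
        df["ct"] = _parse_ct_column(df["ct"], "ct")
        if REPLICATE_COLUMN in df.columns:
            df[REPLICATE_COLUMN] = pd.to_numeric(df[REPLICATE_COLUMN], errors="raise")
        return CTTable(df)
    missing = [c for c in WIDE_ID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"wide layout missing column(s): {missing}")
    gene_cols = [c for c in df.columns if c not in WIDE_ID_COLUMNS]
    if not gene_cols:
        raise SchemaError("wide layout has no gene columns")
    for g in gene_cols:
        df[g] = _parse_ct_column(df[g], g)
    long = df.melt(
        id_vars=list(WIDE_ID_COLUMNS), value_vars=gene_cols,
        var_name="gene", value_name="ct",
    )
    # preserve sample-major ordering with genes in column order
    long["_s"] = long["sample"].map({s: i for i, s in enumerate(dict.fromkeys(df["sample"]))})
    long["_g"] = long["gene"].map({g: i for i, g in enumerate(gene_cols)})
    long = long.sort_values(["_s", "_g"]).drop(columns=["_s", "_g"])
    return CTTable(long)


def write_ct_table(table: CTTable, path, layout: str = "wide") -> None:
    """Write a CT table to CSV; missing cells become empty fields."""
    if layout == "long":
        cols = list(LONG_COLUMNS)
        if table.has_replicates:
            cols.append(REPLICATE_COLUMN)
        table.data[cols].to_csv(path, index=False, na_rep="")
    elif layout == "wide":
        mat = table.wide()  # raises if uncollapsed replicates
        out = table.annotations.join(mat).reset_index()
        out.to_csv(path, index=False, na_rep="")
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
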