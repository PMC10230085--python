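"""Tabular I/O: Ct tables (wide/long), TPM matrices, result writers, fixtures.

All files are plain UTF-8 CSV/TSV with a mandatory header row; the delimiter
is inferred from the file extension (``.tsv`` -> tab, otherwise comma).
Some qPCR exports use a decimal comma; ``decimal_comma=True`` converts on
read.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import TpmMatrix
from .stability import CtMatrix, StabilityTable, reduce_replicates

__all__ = [
    "read_tissue_map",
    "read_ct_table",
    "write_ct_table",
    "read_tpm_table",
    "write_table",
    "write_stability_table",
    "load_table1_fixture",
]

_TABLE1_SHA256 = "1feee66854b350e9fd3868bff4537349f0ac742b7fda069e908fa3ed4a1ed68c"

_LONG_COLUMNS = ["sample", "gene", "replicate", "ct"]


def _sep(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_tissue_map(path) -> pd.Series:
    """Two-column sample -> tissue table."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError("tissue map needs two columns: sample, tissue")
    df = df.iloc[:, :2]
    df.columns = ["sample", "tissue"]
    if df["sample"].duplicated().any():
        dupes = sorted(df.loc[df["sample"].duplicated(), "sample"])
        raise ValueError(f"duplicate samples in tissue map: {dupes}")
    return df.set_index("sample")["tissue"]


def read_ct_table(path, dialect: str = "wide", tissue: pd.Series | None = None,
                  efficiency: pd.Series | None = None,
                  decimal_comma: bool = False) -> CtMatrix:
    """Parse a Ct table.

    ``wide``: first column gene IDs, remaining columns one mean Ct per
    sample. ``long``: columns ``sample, gene, replicate, ct`` (technical
    replicates preserved and averaged to the mean-Ct matrix).
    """
    decimal = "," if decimal_comma else "."
    sep = _sep(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0, decimal=decimal)
        _require_numeric(df, path)
        if df.index.has_duplicates:
            raise ValueError("duplicate gene IDs in wide Ct table")
        df.index.name = None
        df.columns.name = None
        return CtMatrix(df.astype(float), tissue=tissue, efficiency=efficiency)
    if dialect == "long":
        df = pd.read_csv(path, sep=sep, decimal=decimal)
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long Ct table missing columns: {missing}")
        bad = pd.to_numeric(df["ct"], errors="coerce").isna() & df["ct"].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(f"non-numeric Ct at row {row} of {path}")
        if df["ct"].isna().any():
            row = int(df.index[df["ct"].isna()][0]) + 2
            raise ValueError(f"missing Ct at row {row} of {path}")
        df["ct"] = pd.to_numeric(df["ct"])
        keys = df[["gene", "sample", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (gene, sample, replicate) key: {dup}")
        return reduce_replicates(df, tissue=tissue, efficiency=efficiency)
    raise ValueError(f"unknown Ct table dialect: {dialect!r}")


def _require_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = list(df.index).index(df.index[bad][0]) + 2
            raise ValueError(f"non-numeric Ct at row {row} of {path}")


def write_ct_table(ct: CtMatrix, path) -> None:
    """Write the mean-Ct matrix in the wide dialect."""
    out = ct.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sep(path))


def read_tpm_table(path, tissue_map_path=None, tissue: pd.Series | None = None,
                   gene_name: pd.Series | None = None) -> TpmMatrix:
    """Wide TPM table: first column transcript ID, header row = sample IDs."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index.name = None
    df.columns.name = None
    if tissue is None:
        if tissue_map_path is None:
            raise ValueError("a tissue map (path or Series) is required")
        tissue = read_tissue_map(tissue_map_path)
    return TpmMatrix(df.astype(float), tissue=tissue, gene_name=gene_name,
                     annotated=None if gene_name is None else gene_name.notna())


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep(path), index=index)


def write_stability_table(table: StabilityTable, path) -> None:
    write_table(table.to_frame(), path)


def load_table1_fixture(validate_checksum: bool = True) -> pd.DataFrame:
    """Packaged candidate table from the in-silico transcriptome screen.

    Columns: ``transcript_id, group, gene, accession, cv_percent``. The
    in-silico groups are Nervous/Adult/Arm/Brain (77 rows, 69 unique
    transcripts); 8 further rows carry the group label ``Published`` for
    reference genes taken from earlier cephalopod studies.
    """
    ref = resources.files("refstab").joinpath("data/table1_cv.tsv")
    raw = ref.read_bytes()
    if validate_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise RuntimeError(
                "packaged fixture table1_cv.tsv is corrupted "
                f"(sha256 {digest} != {_TABLE1_SHA256})"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t")
    df["cv_percent"] = df["cv_percent"].astype(float)
    return df
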