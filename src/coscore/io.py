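"""Readers and writers for the pipeline's tab-separated interchange formats.

All tables are TSV with a header row.  Coordinates in fusion tables are
0-based; intervals are half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError
from .fusions import CALL_COLUMNS


def read_expression(path) -> pd.DataFrame:
    """Samples × features log2 expression table; first column is sample id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expression table needs a sample id column plus features")
    return df.set_index(df.columns[0]).rename_axis("sample_id")


def write_expression(df: pd.DataFrame, path) -> None:
    df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "endpoint", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: clinical table lacks columns {sorted(missing)}")
    return df


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_fusion_calls(path) -> pd.DataFrame:
    """Fusion call TSV in the canonical schema, or BEDPE (10+ columns).

    BEDPE rows (chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2) use name = "gene5p:gene3p" and score = supporting reads.
    """
    head = pd.read_csv(path, sep="\t", nrows=1)
    if "gene5p" in head.columns:
        df = pd.read_csv(path, sep="\t")
        missing = set(CALL_COLUMNS) - set(df.columns) - {"replicate_id"}
        if missing:
            raise DataError(f"{path}: fusion table lacks columns {sorted(missing)}")
        if "replicate_id" not in df.columns:
            df["replicate_id"] = Path(path).stem
        return df
    bedpe = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bedpe.shape[1] < 10:
        raise DataError(f"{path}: not a recognised fusion call table")
    names = bedpe[6].astype(str).str.split(":", n=1, expand=True)
    if names.shape[1] < 2 or names.isna().any().any():
        raise DataError(f"{path}: BEDPE name column must be 'gene5p:gene3p'")
    return pd.DataFrame(
        {
            "replicate_id": Path(path).stem,
            "gene5p": names[0],
            "chrom5p": bedpe[0],
            "breakpoint5p": bedpe[1],
            "strand5p": bedpe[8],
            "gene3p": names[1],
            "chrom3p": bedpe[3],
            "breakpoint3p": bedpe[4],
            "strand3p": bedpe[9],
            "support_reads": pd.to_numeric(bedpe[7], errors="coerce").fillna(0).astype(int),
        }
    )
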