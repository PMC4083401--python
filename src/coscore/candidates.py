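"""Candidate-target selection from differential-expression result tables.

Thresholds follow the discovery analysis: FDR < 0.1 and |log2 fold change| > 1,
with strict inequalities — rows sitting exactly on a threshold are excluded.
The DE engines themselves (DESeq for genes, DEXSeq for exons) are upstream
tools whose result tables this module consumes; ``normalize_de_columns``
adapts their column names.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("feature_id", "log2fc", "fdr")

# Column aliases seen in DESeq / DEXSeq output tables.
_ALIASES = {
    "log2foldchange": "log2fc",
    "log2fold": "log2fc",
    "padj": "fdr",
    "padjust": "fdr",
    "qvalue": "fdr",
    "pval": "pvalue",
    "p_value": "pvalue",
    "geneid": "feature_id",
    "groupid": "gene_id",
}


def normalize_de_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Rename DESeq/DEXSeq-style columns to the canonical DE schema."""
    renamed = table.rename(columns=lambda c: _ALIASES.get(c.strip().lower(), c.strip().lower()))
    missing = [c for c in REQUIRED_COLUMNS if c not in renamed.columns]
    if missing:
        raise DataError(f"DE table lacks required columns after normalization: {missing}")
    return renamed


def filter_gene_level(
    records: pd.DataFrame,
    fdr_max: float = 0.1,
    lfc_min: float = 1.0,
    direction: str = "up",
) -> pd.DataFrame:
    """Retain gene-level DE rows passing the strict FDR and fold-change cuts.

    direction="up" keeps log2fc > lfc_min (increased expression in tumors);
    direction="both" keeps |log2fc| > lfc_min.
    """
    if direction not in ("up", "both"):
        raise DataError(f"direction must be 'up' or 'both', got {direction!r}")
    if records.empty:
        logger.warning("gene-level filter received an empty DE table")
        return records.copy()
    fdr_ok = records["fdr"] < fdr_max
    if direction == "up":
        lfc_ok = records["log2fc"] > lfc_min
    else:
        lfc_ok = records["log2fc"].abs() > lfc_min
    return records[fdr_ok & lfc_ok].copy()


def filter_exon_level(
    records: pd.DataFrame,
    fdr_max: float = 0.1,
    lfc_min: float = 1.0,
    require_lfc: bool = True,
) -> list:
    """Genes with at least one differentially used exon.

    An exon qualifies with fdr < fdr_max and, when ``require_lfc`` (the
    default, matching the discovery criteria), |log2fc| > lfc_min; the
    FDR-only mode covers the looser reading where only the FDR cut applies.
    Returns the sorted gene identifiers, duplicates collapsed.
    """
    if "gene_id" not in records.columns:
        raise DataError("exon-level records need a 'gene_id' grouping column")
    if records["gene_id"].isna().any():
        raise DataError("exon-level records contain exons without a gene key")
    keep = records["fdr"] < fdr_max
    if require_lfc:
        keep &= records["log2fc"].abs() > lfc_min
    return sorted(records.loc[keep, "gene_id"].unique())


def annotate_compartment(
    features,
    annotation: pd.DataFrame,
    require_ortholog: bool = True,
) -> list:
    """Keep features encoding secreted or plasma-membrane proteins.

    Features absent from the annotation are treated as compartment "other"
    (and logged), hence dropped.  With ``require_ortholog`` a non-empty
    human_ortholog entry is also required.
    """
    ann = annotation.set_index("feature_id")
    kept = []
    for feat in features:
        if feat not in ann.index:
            logger.warning("feature %s missing from annotation; treated as 'other'", feat)
            continue
        row = ann.loc[feat]
        if row["compartment"] not in ("plasma_membrane", "secreted"):
            continue
        if require_ortholog:
            ortholog = row.get("human_ortholog", "")
            if pd.isna(ortholog) or str(ortholog).strip() == "":
                continue
        kept.append(feat)
    return kept
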