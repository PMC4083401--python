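"""Post-filtering of putative gene-fusion calls from tumor/normal RNA-seq.

Fusion callers are error prone, so putative chimeric transcripts are kept
only when (1) concordant across tumor (MT) replicates, (2) absent from every
wild-type (WT) replicate, and (3) not explainable as a read-through
transcript (adjacent same-strand genes in transcriptional order within a gap
limit) or as a fusion between homologous genes — both typical artifacts.

Event identity is the ordered (5' gene, 3' gene) symbol pair: callers report
multiple breakpoints per pair and the biology is argued at gene-pair level.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "replicate_id", "gene5p", "chrom5p", "breakpoint5p", "strand5p",
    "gene3p", "chrom3p", "breakpoint3p", "strand3p", "support_reads",
]

READTHROUGH_MAX_GAP = 200_000  # bases; declared convention, configurable


def _pair_key(df: pd.DataFrame) -> pd.Series:
    return df["gene5p"].astype(str) + "\t" + df["gene3p"].astype(str)


def intersect_replicates(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame) -> pd.DataFrame:
    """Calls whose ordered (gene5p, gene3p) pair occurs in both replicates.

    Symmetric in its arguments: one row per common pair, with support_reads
    reduced to the minimum across the replicates (the conservative evidence).
    """
    if calls_rep1.empty or calls_rep2.empty:
        return calls_rep1.iloc[0:0].copy()
    merged = pd.concat([calls_rep1, calls_rep2], ignore_index=True)
    # sort rows so the representative picked per pair is argument-order-free
    merged = merged.sort_values(list(merged.columns), kind="stable").reset_index(drop=True)
    k1, k2 = set(_pair_key(calls_rep1)), set(_pair_key(calls_rep2))
    common = merged[_pair_key(merged).isin(k1 & k2)]
    agg = {c: "first" for c in common.columns if c != "support_reads"}
    if "support_reads" in common.columns:
        agg["support_reads"] = "min"
    out = (
        common.groupby(["gene5p", "gene3p"], as_index=False, sort=True)
        .agg({k: v for k, v in agg.items() if k not in ("gene5p", "gene3p")})
    )
    return out[[c for c in common.columns if c in out.columns]].reset_index(drop=True)


def subtract_control(mt_common: pd.DataFrame, wt_calls) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove pairs seen in ANY wild-type replicate (the conservative reading).

    Returns ``(tumor_specific, control_shared)``.
    """
    if isinstance(wt_calls, pd.DataFrame):
        wt_calls = [wt_calls]
    wt_pairs: set = set()
    for wt in wt_calls:
        if not wt.empty:
            wt_pairs |= set(_pair_key(wt))
    if mt_common.empty or not wt_pairs:
        return mt_common.copy(), mt_common.iloc[0:0].copy()
    shared_mask = _pair_key(mt_common).isin(wt_pairs)
    return mt_common[~shared_mask].copy(), mt_common[shared_mask].copy()


def classify_artifact(
    gene5p: str,
    gene3p: str,
    models: pd.DataFrame,
    readthrough_max_gap: int = READTHROUGH_MAX_GAP,
) -> str:
    """Classify one gene pair as read_through, homologue_pair or retained.

    Read-through: same chromosome, same strand, non-overlapping, with the 5'
    partner upstream of the 3' partner in transcriptional orientation and a
    genomic gap of at most ``readthrough_max_gap`` bases.  Homologue pair:
    both genes share a non-empty homology_group.  Anything else is a genuine
    candidate and is retained.
    """
    idx = models.set_index("gene_id") if models.index.name != "gene_id" else models
    missing = [g for g in (gene5p, gene3p) if g not in idx.index]
    if missing:
        raise DataError(f"gene(s) missing from gene models: {missing}")
    a, b = idx.loc[gene5p], idx.loc[gene3p]

    hg_a = str(a.get("homology_group", "") or "").strip()
    hg_b = str(b.get("homology_group", "") or "").strip()
    if hg_a and hg_a != "nan" and hg_a == hg_b:
        return "homologue_pair"

    if a["chrom"] == b["chrom"] and a["strand"] == b["strand"]:
        if a["strand"] == "+":
            upstream_ok = a["end"] <= b["start"]
            gap = b["start"] - a["end"]
        else:
            upstream_ok = b["end"] <= a["start"]
            gap = a["start"] - b["end"]
        if upstream_ok and 0 <= gap <= readthrough_max_gap:
            return "read_through"
    return "retained"


def run_fusion_filter(
    mt_reps,
    wt_reps,
    models: pd.DataFrame,
    readthrough_max_gap: int = READTHROUGH_MAX_GAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate intersection → WT subtraction → artifact classification.

    Returns ``(audit, retained)``: the audit table carries every
    replicate-common pair with its ``classification`` (control_shared,
    read_through, homologue_pair, retained, or unclassifiable when a partner
    is missing from the gene models — such calls are kept but flagged);
    ``retained`` is the subset of genuine tumor-specific candidates.
    """
    mt_reps = [mt_reps] if isinstance(mt_reps, pd.DataFrame) else list(mt_reps)
    if not mt_reps:
        raise DataError("at least one tumor replicate is required")
    if len(mt_reps) == 1:
        logger.warning("single tumor replicate: intersection step is the identity")
        common = mt_reps[0].copy()
    else:
        common = mt_reps[0]
        for rep in mt_reps[1:]:
            common = intersect_replicates(common, rep)

    tumor_specific, control_shared = subtract_control(common, wt_reps)

    classifications = []
    for _, row in tumor_specific.iterrows():
        try:
            cls = classify_artifact(
                row["gene5p"], row["gene3p"], models, readthrough_max_gap
            )
        except DataError as err:
            logger.warning("unclassifiable call %s:%s (%s); kept, flagged",
                           row["gene5p"], row["gene3p"], err)
            cls = "unclassifiable"
        classifications.append(cls)
    tumor_specific = tumor_specific.assign(classification=classifications)
    control_shared = control_shared.assign(classification="control_shared")

    audit = pd.concat([tumor_specific, control_shared], ignore_index=True)
    audit = audit.sort_values(["gene5p", "gene3p"], kind="stable").reset_index(drop=True)
    retained = audit[audit["classification"].isin(["retained", "unclassifiable"])]
    return audit, retained.reset_index(drop=True)
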