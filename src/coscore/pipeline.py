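"""End-to-end orchestration: candidates → harmonize → CO score (+ fusions).

The pipeline mirrors the discovery logic: select up-regulated candidates
from DE tables, restrict to secreted/membrane genes with a human ortholog,
harmonize the clinical meta-cohort, split it into test and validation
groups, and score every candidate per endpoint in each split — on all
samples and on the early-stage (T1) subset — requiring a hit to replicate
in both splits.  A manifest records seeds and parameters for exact
reproduction; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import candidates, cohort, fusions, io
from .errors import DataError, ValidationError
from .score import ScoreConfig, evaluate_dataset

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    expression: str = ""
    clinical: str = ""
    de_gene: str = ""
    annotation: str = ""           # compartment/ortholog annotation (optional)
    fusion_mt: list = field(default_factory=list)
    fusion_wt: list = field(default_factory=list)
    gene_models: str = ""
    outdir: str = "results/pipeline"
    score: ScoreConfig = field(default_factory=ScoreConfig)
    fdr_max: float = 0.1
    lfc_min: float = 1.0
    direction: str = "up"
    require_ortholog: bool = True
    year_threshold: int = 2009
    stage_category: str = "T1"
    readthrough_max_gap: int = fusions.READTHROUGH_MAX_GAP
    overwrite: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        score = ScoreConfig(**raw.pop("score", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline config fields: {sorted(unknown)}")
        return cls(score=score, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns {output name: path}."""
    for name in ("expression", "clinical"):
        if not getattr(config, name):
            raise ValidationError(f"pipeline config is missing required field: {name}")
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise DataError(f"output directory {outdir} is not empty (overwrite disabled)")
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    expr = io.read_expression(config.expression)
    clin = io.read_clinical(config.clinical)

    # --- candidate selection -------------------------------------------------
    if config.de_gene:
        de = candidates.normalize_de_columns(io.read_table(config.de_gene))
        selected = candidates.filter_gene_level(
            de, fdr_max=config.fdr_max, lfc_min=config.lfc_min, direction=config.direction
        )
        feats = list(selected["feature_id"].astype(str))
        if config.annotation:
            ann = io.read_table(config.annotation)
            feats = candidates.annotate_compartment(
                feats, ann, require_ortholog=config.require_ortholog
            )
        io.write_table(selected.assign(candidate=selected["feature_id"].astype(str).isin(feats)),
                       outdir / "candidates.tsv")
        outputs["candidates"] = str(outdir / "candidates.tsv")
        scored_features = [f for f in feats if f in expr.columns]
        if not scored_features:
            raise DataError("no candidate features present in the expression table")
        expr = expr[scored_features]

    # --- fusion filtering ----------------------------------------------------
    if config.fusion_mt:
        models = io.read_table(config.gene_models)
        mt = [io.read_fusion_calls(p) for p in config.fusion_mt]
        wt = [io.read_fusion_calls(p) for p in config.fusion_wt]
        audit, retained = fusions.run_fusion_filter(
            mt, wt, models, readthrough_max_gap=config.readthrough_max_gap
        )
        io.write_table(audit, outdir / "fusion_audit.tsv")
        io.write_table(retained, outdir / "fusion_retained.tsv")
        outputs["fusion_audit"] = str(outdir / "fusion_audit.tsv")
        outputs["fusion_retained"] = str(outdir / "fusion_retained.tsv")

    # --- split and score -----------------------------------------------------
    test, validation = cohort.split_test_validation(clin, config.year_threshold)
    splits = {"test": test, "validation": validation}
    for split_name, split_clin in splits.items():
        if split_clin.empty:
            logger.warning("%s split is empty; skipped", split_name)
            continue
        for subset_name, stage in (("all", None), (config.stage_category, config.stage_category)):
            try:
                table = evaluate_dataset(expr, split_clin, config.score, stage_filter=stage)
            except DataError as err:
                logger.warning("scoring %s/%s skipped: %s", split_name, subset_name, err)
                continue
            path = outdir / f"co_{split_name}_{subset_name}.tsv"
            io.write_table(table, path)
            if not table.attrs["skipped"].empty:
                io.write_table(table.attrs["skipped"], outdir / f"skipped_{split_name}_{subset_name}.tsv")
            outputs[f"co_{split_name}_{subset_name}"] = str(path)

    manifest = {
        "package_version": __version__,
        "config": _manifest_config(config),
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = str(outdir / "manifest.json")
    return outputs


def _manifest_config(config: PipelineConfig) -> dict:
    raw = asdict(config)
    raw["score"] = asdict(config.score)
    return raw


def cross_split_hits(test_table: pd.DataFrame, validation_table: pd.DataFrame,
                     threshold: float = 0.05) -> pd.DataFrame:
    """Features significant (CO ≤ threshold) in BOTH splits, per endpoint.

    Implements the replication requirement: a candidate only counts when the
    association holds in the test and the validation group alike.
    """
    key = ["feature_id", "endpoint"]
    t = test_table.loc[test_table["co"] <= threshold, key]
    v = validation_table.loc[validation_table["co"] <= threshold, key]
    return t.merge(v, on=key).sort_values(key, kind="stable").reset_index(drop=True)
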