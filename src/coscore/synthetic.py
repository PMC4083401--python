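"""Synthetic cohorts, DE tables and fusion-call fixtures with known truth.

The generator emulates the statistical structure the scoring pipeline
assumes, at the scale of the real meta-cohort it stands in for (989 NSCLC
samples, 74 candidate genes, a handful of real hits):

* per-feature expression is a two-component Gaussian mixture on the log2
  scale (the UP component higher by ``mixture_delta``);
* "true" target features share one latent risk-group assignment: a sample's
  membership drives both those features' expression component and its hazard
  (baseline_rate for DOWN, baseline_rate × hazard_ratio for UP).  Null
  features get independent mixture labels, so their expression carries no
  outcome information;
* event times are exponential per endpoint, administratively right-censored
  at ``censor_time``;
* every random draw flows from the config seed through per-purpose
  sub-streams, so adding features does not shift other features' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

_STREAM_RISK = 0
_STREAM_FEATURE = 1
_STREAM_OUTCOME = 2
_STREAM_META = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the meta-analysis setting the generator emulates: 989
    samples, 74 candidate features of which a few are real prognostic hits,
    follow-up in months with a five-year administrative horizon.
    """

    n_samples: int = 989
    n_features: int = 74
    frac_true: float = 3 / 74
    hazard_ratio: float = 2.0
    baseline_rate: float = 0.02
    mixture_delta: float = 2.0
    mixture_sd: float = 1.0
    frac_up: float = 0.3
    censor_time: float = 60.0
    endpoint_types: tuple = ("survival", "metastasis")
    seed: int = 0
    cohort_years: tuple = (2006, 2008, 2012)
    frac_t1: float = 0.4

    def __post_init__(self):
        checks = [
            ("n_samples", self.n_samples >= 1),
            ("n_features", self.n_features >= 1),
            ("frac_true", 0.0 <= self.frac_true <= 1.0),
            ("hazard_ratio", self.hazard_ratio > 0 and math.isfinite(self.hazard_ratio)),
            ("baseline_rate", self.baseline_rate > 0 and math.isfinite(self.baseline_rate)),
            ("mixture_delta", self.mixture_delta >= 0 and math.isfinite(self.mixture_delta)),
            ("mixture_sd", self.mixture_sd > 0 and math.isfinite(self.mixture_sd)),
            ("frac_up", 0.0 < self.frac_up < 1.0),
            ("censor_time", self.censor_time > 0),
            ("endpoint_types", set(self.endpoint_types) <= {"survival", "metastasis"}
             and len(self.endpoint_types) >= 1),
            ("frac_t1", 0.0 <= self.frac_t1 <= 1.0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValidationError(f"invalid SimulationConfig field: {name}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated tables plus the ground truth used to make them."""

    expression: pd.DataFrame  # samples × features, log2 scale
    clinical: pd.DataFrame    # long: sample_id, endpoint, time, event, stage, cohort, pub_year
    truth: pd.DataFrame       # feature_id, is_true_target, true_hazard_ratio
    latent_labels: pd.DataFrame = field(repr=False)  # samples × features, "UP"/"DOWN"


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate expression, clinical and truth tables for one cohort."""
    n, p = config.n_samples, config.n_features
    sample_ids = [f"S{i:05d}" for i in range(n)]
    feature_ids = [f"feat_{j:04d}" for j in range(p)]
    n_true = int(round(config.frac_true * p))
    is_true = np.zeros(p, dtype=bool)
    is_true[:n_true] = True  # deterministic: first n_true features are the targets

    # One shared latent risk group drives every true feature and the hazard.
    risk_up = _rng(config.seed, _STREAM_RISK).random(n) < config.frac_up

    expr = np.empty((n, p))
    latent = np.empty((n, p), dtype=bool)
    mu_down, mu_up = 0.0, config.mixture_delta
    for j in range(p):
        stream = _rng(config.seed, _STREAM_FEATURE, j)
        up = risk_up if is_true[j] else stream.random(n) < config.frac_up
        noise = stream.normal(0.0, config.mixture_sd, size=n)
        expr[:, j] = np.where(up, mu_up, mu_down) + noise
        latent[:, j] = up

    meta = _rng(config.seed, _STREAM_META)
    stage = np.where(meta.random(n) < config.frac_t1, "T1", "T2")
    cohorts = meta.integers(0, len(config.cohort_years), size=n)
    pub_year = np.asarray(config.cohort_years)[cohorts]
    cohort_name = np.array([f"cohort_{y}" for y in pub_year])

    # Hazard follows the shared risk group only when true targets exist;
    # otherwise outcomes are pure noise, independent of all expression.
    hazard_up = config.hazard_ratio if n_true > 0 else 1.0
    rate = np.where(risk_up, config.baseline_rate * hazard_up, config.baseline_rate)

    clin_rows = []
    for k, endpoint in enumerate(config.endpoint_types):
        stream = _rng(config.seed, _STREAM_OUTCOME, k)
        latent_time = stream.exponential(1.0 / rate)
        time = np.minimum(latent_time, config.censor_time)
        event = (latent_time <= config.censor_time).astype(int)
        clin_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "endpoint": endpoint,
                    "time": time,
                    "event": event,
                    "stage": stage,
                    "cohort": cohort_name,
                    "pub_year": pub_year,
                }
            )
        )

    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "is_true_target": is_true,
            "true_hazard_ratio": np.where(is_true, config.hazard_ratio, 1.0),
        }
    )
    label_df = pd.DataFrame(
        np.where(latent, "UP", "DOWN"), index=sample_ids, columns=feature_ids
    )
    expression = pd.DataFrame(expr, index=sample_ids, columns=feature_ids)
    expression.index.name = "sample_id"
    label_df.index.name = "sample_id"
    return SyntheticCohort(
        expression=expression,
        clinical=pd.concat(clin_rows, ignore_index=True),
        truth=truth,
        latent_labels=label_df,
    )


def generate_de_table(
    n_pass: int, n_fail_fdr: int, n_fail_lfc: int, n_down: int, seed: int = 0,
    level: str = "gene",
) -> pd.DataFrame:
    """DE result table with a known pass/fail status per row.

    Exactly ``n_pass`` rows survive the up-regulated filter (fdr < 0.1 and
    log2fc > 1).  Boundary rows — fdr exactly 0.1 and log2fc exactly 1 — are
    planted among the failing rows to pin the strict-inequality tie-breaking.
    ``n_down`` rows are strongly down-regulated at excellent FDR, so they
    pass only a two-sided filter.
    """
    for name, v in [("n_pass", n_pass), ("n_fail_fdr", n_fail_fdr),
                    ("n_fail_lfc", n_fail_lfc), ("n_down", n_down)]:
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def add(status, log2fc, fdr):
        rows.append(
            {
                "feature_id": f"{level[0]}{len(rows):04d}",
                "gene_id": f"gene_{len(rows):04d}",
                "level": level,
                "log2fc": log2fc,
                "pvalue": min(fdr, 1.0) * rng.uniform(0.2, 1.0),
                "fdr": fdr,
                "planted_status": status,
            }
        )

    for _ in range(n_pass):
        add("pass", rng.uniform(1.2, 6.0), rng.uniform(1e-6, 0.09))
    for i in range(n_fail_fdr):
        # first failing row sits exactly on the FDR boundary
        add("fail_fdr", rng.uniform(1.2, 6.0), 0.1 if i == 0 else rng.uniform(0.11, 0.9))
    for i in range(n_fail_lfc):
        # first failing row sits exactly on the log2FC boundary
        add("fail_lfc", 1.0 if i == 0 else rng.uniform(0.0, 0.9), rng.uniform(1e-6, 0.09))
    for _ in range(n_down):
        add("down", -rng.uniform(1.2, 6.0), rng.uniform(1e-6, 0.09))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "gene_id", "level", "log2fc", "pvalue", "fdr", "planted_status"],
    )


def generate_fusion_fixture(
    n_common: int = 3,
    n_mt_only_single: int = 2,
    n_wt_shared: int = 2,
    n_readthrough: int = 0,
    n_homologue: int = 0,
    seed: int = 0,
):
    """Fusion-call tables with planted event classes and the expected survivors.

    Plants ``n_common`` genuine inter-chromosomal events in both tumor (MT)
    replicates, ``n_mt_only_single`` events in one MT replicate only,
    ``n_wt_shared`` events shared with wild-type, and — also common to both
    MT replicates — ``n_readthrough`` adjacent same-strand pairs and
    ``n_homologue`` pairs sharing a homology group.  Returns
    ``(mt_reps, wt_reps, annotation, expected_retained)`` where
    ``expected_retained`` is the set of (gene5p, gene3p) pairs a correct
    filter keeps: the common events that are neither read-through nor
    homologue pairs.
    """
    for name, v in [("n_common", n_common), ("n_mt_only_single", n_mt_only_single),
                    ("n_wt_shared", n_wt_shared), ("n_readthrough", n_readthrough),
                    ("n_homologue", n_homologue)]:
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    genes, calls = [], []
    counter = {"g": 0}

    def new_gene(chrom, start, strand, homology_group=""):
        gid = f"Gene{counter['g']:03d}"
        counter["g"] += 1
        genes.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": start,
                "end": start + 20_000,
                "strand": strand,
                "homology_group": homology_group,
            }
        )
        return gid

    def call(rep, g5, g3):
        a = next(g for g in genes if g["gene_id"] == g5)
        b = next(g for g in genes if g["gene_id"] == g3)
        calls.append(
            {
                "replicate_id": rep,
                "gene5p": g5,
                "chrom5p": a["chrom"],
                "breakpoint5p": a["end"] - 1,
                "strand5p": a["strand"],
                "gene3p": g3,
                "chrom3p": b["chrom"],
                "breakpoint3p": b["start"],
                "strand3p": b["strand"],
                "support_reads": int(rng.integers(3, 60)),
            }
        )

    expected = set()
    chrom_pool = [f"chr{c}" for c in range(1, 20)]

    def genuine_pair():
        c5, c3 = rng.choice(chrom_pool, size=2, replace=False)
        g5 = new_gene(c5, int(rng.integers(1e6, 5e7)), rng.choice(["+", "-"]))
        g3 = new_gene(c3, int(rng.integers(1e6, 5e7)), rng.choice(["+", "-"]))
        return g5, g3

    for _ in range(n_common):
        g5, g3 = genuine_pair()
        call("MT1", g5, g3)
        call("MT2", g5, g3)
        expected.add((g5, g3))
    for _ in range(n_readthrough):
        chrom = rng.choice(chrom_pool)
        strand = rng.choice(["+", "-"])
        start = int(rng.integers(1e6, 5e7))
        up = new_gene(chrom, start, strand)
        dn = new_gene(chrom, start + 50_000, strand)  # 30 kb gap, well inside the limit
        g5, g3 = (up, dn) if strand == "+" else (dn, up)
        call("MT1", g5, g3)
        call("MT2", g5, g3)
    for _ in range(n_homologue):
        group = f"HG{rng.integers(0, 10**6):06d}"
        c5, c3 = rng.choice(chrom_pool, size=2, replace=False)
        g5 = new_gene(c5, int(rng.integers(1e6, 5e7)), rng.choice(["+", "-"]), group)
        g3 = new_gene(c3, int(rng.integers(1e6, 5e7)), rng.choice(["+", "-"]), group)
        call("MT1", g5, g3)
        call("MT2", g5, g3)
    for i in range(n_mt_only_single):
        g5, g3 = genuine_pair()
        call("MT1" if i % 2 == 0 else "MT2", g5, g3)
    for _ in range(n_wt_shared):
        g5, g3 = genuine_pair()
        call("MT1", g5, g3)
        call("MT2", g5, g3)
        call("WT1", g5, g3)

    columns = [
        "replicate_id", "gene5p", "chrom5p", "breakpoint5p", "strand5p",
        "gene3p", "chrom3p", "breakpoint3p", "strand3p", "support_reads",
    ]
    call_df = pd.DataFrame(calls, columns=columns)
    mt_reps = [
        call_df[call_df["replicate_id"] == rep].reset_index(drop=True)
        for rep in ("MT1", "MT2")
    ]
    wt_reps = [
        call_df[call_df["replicate_id"] == rep].reset_index(drop=True)
        for rep in ("WT1",)
    ]
    annotation = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand", "homology_group"]
    )
    return mt_reps, wt_reps, annotation, expected
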