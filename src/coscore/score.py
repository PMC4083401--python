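"""Clinical Outcome (CO) scoring of features against censored outcomes.

For each feature × endpoint the procedure is:

1. dichotomize the feature's expression into UP/DOWN by exact 1-D 2-means;
2. compute P_true, the χ²(1) LRT significance of separate UP/DOWN exponential
   survival rates versus a pooled rate, on the full sample;
3. build a null distribution P*₁..P*ₙ: at each of n repetitions remove a
   fixed fraction of samples uniformly at random, permute the observed
   UP/DOWN labels among the retained samples (label counts preserved), and
   recompute the same LRT significance;
4. CO = |{i : P*ᵢ ≤ P_true}| / n_effective — the empirical permutation
   p-value.  Small CO means the observed association is both strong and
   robust to removing samples.  The complement 1 − CO is reported alongside
   as a robustness score (larger = better) so either orientation is at hand.

Repetitions where the permuted relabelling leaves a group empty or without
exposure are dropped and counted; n_effective is the denominator actually
used.  All randomness flows from a master seed through per-(feature,
endpoint) sub-streams derived by hashing, so results do not depend on the
order in which features are scored.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dichotomize import kmeans_dichotomize
from .errors import DataError, DegenerateInputError, UnscorableError, ValidationError
from .survival import compare_groups, exp_loglik, sanitize_times

logger = logging.getLogger(__name__)

ENDPOINTS = ("survival", "metastasis")

# Repetitions are processed in chunks of this many rows to bound the size of
# the (repetitions × samples) work matrices at cohort scale.
_CHUNK = 2000


@dataclass(frozen=True)
class ScoreConfig:
    """Parameters of the permutation/subsampling null.

    n_repetitions : number of null repetitions (default 10000).
    removal_fraction : fraction of samples removed, without replacement, at
        each repetition (default 0.10); the removal count is
        floor(removal_fraction × n_samples).
    min_cluster_size : smallest admissible 2-means cluster (default 1 —
        single-sample high-expression clusters are allowed, as real cohorts
        produce them).
    iid_relabel : if True, draw null labels i.i.d. Bernoulli(observed UP
        frequency) instead of permuting the observed label vector.
    per_subsample_p_true : if True, recompute P_true on each retained subset
        (sensitivity mode); by default P_true comes from the full sample.
    """

    n_repetitions: int = 10000
    removal_fraction: float = 0.10
    seed: int = 0
    min_cluster_size: int = 1
    iid_relabel: bool = False
    per_subsample_p_true: bool = False

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if not 0.0 <= self.removal_fraction < 1.0:
            raise ValidationError("removal_fraction must lie in [0, 1)")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class COResult:
    feature_id: str
    endpoint: str
    p_true: float
    p_star: np.ndarray = field(repr=False)
    co: float
    co_complement: float
    n_effective: int
    n_up: int
    n_down: int
    lambda_up: float
    lambda_down: float
    lrt_stat: float
    seed: int


def feature_seed(master_seed: int, feature_id: str, endpoint: str) -> int:
    """Deterministic 31-bit sub-seed for one (feature, endpoint) stream."""
    digest = hashlib.sha256(f"{master_seed}:{feature_id}:{endpoint}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _group_lrt(t, e, up):
    """Row-wise LRT statistics for boolean UP matrices (vectorized)."""
    d_up = (e * up).sum(axis=1)
    T_up = (t * up).sum(axis=1)
    down = ~up
    d_dn = (e * down).sum(axis=1)
    T_dn = (t * down).sum(axis=1)
    ll_split = exp_loglik(d_up, T_up) + exp_loglik(d_dn, T_dn)
    ll_pool = exp_loglik(d_up + d_dn, T_up + T_dn)
    lrt = np.maximum(2.0 * (ll_split - ll_pool), 0.0)
    valid = (up.sum(axis=1) > 0) & (down.sum(axis=1) > 0) & (T_up > 0) & (T_dn > 0)
    return lrt, valid


def permutation_null(times, events, labels, config: ScoreConfig, rng=None):
    """Null distribution of P* under random relabelling with subsampling.

    Returns the vector of valid P* values (length n_effective ≤
    n_repetitions).  Degenerate repetitions — all retained samples in one
    group, or a group with zero exposure — are dropped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    lab = np.asarray(labels)
    up_obs = lab if lab.dtype == bool else lab == "UP"
    n = t.size
    n_keep = n - int(np.floor(config.removal_fraction * n))
    if n_keep < 2:
        raise UnscorableError("fewer than 2 samples retained after removal")
    frac_up = up_obs.mean()

    p_parts = []
    remaining = config.n_repetitions
    while remaining > 0:
        reps = min(remaining, _CHUNK)
        remaining -= reps
        # A uniform random permutation per row; its first n_keep entries are
        # the retained subset.  Gathering labels through `keep` alone would
        # preserve each sample's own label, so the retained labels get an
        # independent within-row shuffle to break the sample-label pairing.
        order = np.argsort(rng.random((reps, n)), axis=1)
        keep = order[:, :n_keep]
        tk = t[keep]
        ek = e[keep]
        if config.iid_relabel:
            up = rng.random((reps, n_keep)) < frac_up
        else:
            shuffle = np.argsort(rng.random((reps, n_keep)), axis=1)
            up = np.take_along_axis(up_obs[keep], shuffle, axis=1)
        lrt, valid = _group_lrt(tk, ek, up)
        if valid.any():
            p_parts.append(stats.chi2.sf(lrt[valid], df=1))
    dropped = config.n_repetitions - sum(p.size for p in p_parts)
    if dropped:
        logger.info("dropped %d degenerate null repetitions", dropped)
    if not p_parts:
        raise UnscorableError("all null repetitions were degenerate")
    return np.concatenate(p_parts)


def compute_co(p_true: float, p_star) -> float:
    """Empirical permutation p-value |{P* ≤ P_true}| / n_effective."""
    p_star = np.asarray(p_star, dtype=float)
    if p_star.size == 0:
        raise UnscorableError("empty P* vector; feature is unscorable")
    return float(np.count_nonzero(p_star <= p_true) / p_star.size)


def evaluate_feature(
    values,
    times,
    events,
    config: ScoreConfig,
    feature_id: str = "",
    endpoint: str = "survival",
) -> COResult:
    """Score one feature against one endpoint's censored outcomes."""
    sub_seed = feature_seed(config.seed, feature_id, endpoint)
    rng = np.random.default_rng(sub_seed)
    dichotomy = kmeans_dichotomize(
        values, feature_id=feature_id, min_cluster_size=config.min_cluster_size
    )
    t = sanitize_times(times)
    e = np.asarray(events, dtype=float)
    observed = compare_groups(t, e, dichotomy.labels)
    if config.per_subsample_p_true:
        p_true = _median_subsample_p_true(t, e, dichotomy.is_up, config, rng)
    else:
        p_true = observed.p_true
    p_star = permutation_null(t, e, dichotomy.is_up, config, rng=rng)
    co = compute_co(p_true, p_star)
    return COResult(
        feature_id=feature_id,
        endpoint=endpoint,
        p_true=p_true,
        p_star=p_star,
        co=co,
        co_complement=1.0 - co,
        n_effective=int(p_star.size),
        n_up=dichotomy.n_up,
        n_down=dichotomy.n_down,
        lambda_up=observed.fit_up.rate,
        lambda_down=observed.fit_down.rate,
        lrt_stat=observed.lrt_stat,
        seed=sub_seed,
    )


def _median_subsample_p_true(t, e, up_obs, config, rng):
    """Sensitivity mode: median of P_true over the removal subsamples."""
    n = t.size
    n_keep = n - int(np.floor(config.removal_fraction * n))
    order = np.argsort(rng.random((config.n_repetitions, n)), axis=1)
    keep = order[:, :n_keep]
    lrt, valid = _group_lrt(t[keep], e[keep], up_obs[keep])
    if not valid.any():
        raise UnscorableError("no valid subsample for per-subsample P_true")
    return float(np.median(stats.chi2.sf(lrt[valid], df=1)))


def evaluate_dataset(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    config: ScoreConfig,
    endpoints=None,
    stage_filter: str | None = None,
) -> pd.DataFrame:
    """Score every feature of an expression table against every endpoint.

    Parameters
    ----------
    expression : samples × features table of log2 expression, indexed by
        sample id (or with a ``sample_id`` column).
    clinical : long table with columns sample_id, endpoint, time, event and
        optionally stage.
    endpoints : endpoints to score; default every endpoint present.
    stage_filter : if given (e.g. "T1"), restrict to samples of that TNM T
        category before scoring.

    Returns a table ranked by (co, p_true) ascending within endpoint, with
    one row per scored feature × endpoint.  Features skipped for degenerate
    dichotomies are recorded in the result's ``attrs["skipped"]``.
    """
    expr = expression.set_index("sample_id") if "sample_id" in expression.columns else expression
    clin = clinical.copy()
    if stage_filter is not None:
        if "stage" not in clin.columns:
            raise DataError("clinical table has no 'stage' column for stage filtering")
        clin = clin[clin["stage"].astype(str) == stage_filter]
        if clin.empty:
            raise DataError(f"no samples with stage {stage_filter!r}")
    if endpoints is None:
        endpoints = [ep for ep in ENDPOINTS if ep in set(clin["endpoint"])]

    rows, skipped = [], []
    for endpoint in endpoints:
        sub = clin[clin["endpoint"] == endpoint]
        common = expr.index.intersection(sub["sample_id"])
        if common.empty:
            raise DataError(f"no overlapping samples between tables for endpoint {endpoint!r}")
        sub = sub.set_index("sample_id").loc[common]
        t = sub["time"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=float)
        for feature in expr.columns:
            values = expr.loc[common, feature].to_numpy(dtype=float)
            try:
                res = evaluate_feature(
                    values, t, e, config, feature_id=str(feature), endpoint=endpoint
                )
            except DegenerateInputError as err:
                skipped.append(
                    {"feature_id": str(feature), "endpoint": endpoint, "reason": f"degenerate dichotomy: {err}"}
                )
                logger.warning("skipping %s/%s: %s", feature, endpoint, err)
                continue
            except UnscorableError as err:
                skipped.append({"feature_id": str(feature), "endpoint": endpoint, "reason": str(err)})
                logger.warning("skipping %s/%s: %s", feature, endpoint, err)
                continue
            rows.append(
                {
                    "feature_id": res.feature_id,
                    "endpoint": res.endpoint,
                    "n_up": res.n_up,
                    "n_down": res.n_down,
                    "lambda_up": res.lambda_up,
                    "lambda_down": res.lambda_down,
                    "p_true": res.p_true,
                    "co": res.co,
                    "co_complement": res.co_complement,
                    "n_effective": res.n_effective,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "endpoint", "n_up", "n_down", "lambda_up",
            "lambda_down", "p_true", "co", "co_complement", "n_effective",
        ],
    )
    out = out.sort_values(
        ["endpoint", "co", "p_true", "feature_id"], kind="stable"
    ).reset_index(drop=True)
    out.attrs["skipped"] = pd.DataFrame(skipped, columns=["feature_id", "endpoint", "reason"])
    return out
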