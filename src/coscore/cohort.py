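"""Multi-cohort clinical harmonization.

Real lung-cancer cohorts annotate outcomes under heterogeneous field names
and units.  This module deduplicates samples, standardizes raw outcome
fields into at most two event types per sample — survival and metastasis —
on a common time scale (months), splits the meta-cohort into test and
validation groups at the whole-cohort level by publication year, and
subsets by TNM T category.  Every standardized record carries a provenance
column naming the raw fields it came from, so no event is ever invented.

The outcome mapping is a plain dict (typically loaded from YAML), e.g.::

    {"cohortA": {"unit": "months",
                 "endpoints": {"survival": {"time": "os_months",
                                            "event": "os_event"},
                               "metastasis": {"time": "mfs_months",
                                              "event": "met_event"}}}}

Event fields may be 0/1 or text; an optional per-endpoint ``event_coding``
maps raw values to 0/1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

_UNIT_TO_MONTHS = {"months": 1.0, "month": 1.0, "years": 12.0, "year": 12.0,
                   "days": 1.0 / 30.44, "day": 1.0 / 30.44}

CLINICAL_COLUMNS = [
    "sample_id", "endpoint", "time", "event", "stage", "cohort", "pub_year", "provenance",
]


def deduplicate(samples: pd.DataFrame, outcome_fields, cohort_priority=None):
    """One record per sample_id; samples with no usable outcome removed.

    ``outcome_fields`` are the raw columns that can carry outcome
    information; a sample with all of them missing is dropped.  Duplicate
    ids with conflicting outcome values are resolved by ``cohort_priority``
    (first cohort in the list wins; default: input order) and reported.
    Returns ``(unique_samples, report)`` where report counts removals.
    """
    df = samples.copy()
    present = [f for f in outcome_fields if f in df.columns]
    if not present:
        raise DataError(f"none of the outcome fields {list(outcome_fields)} are present")
    has_outcome = df[present].notna().any(axis=1)
    n_no_outcome = int((~has_outcome).sum())
    df = df[has_outcome]

    if cohort_priority is not None:
        rank = {c: i for i, c in enumerate(cohort_priority)}
        df = df.assign(_rank=df["cohort"].map(rank).fillna(len(rank)))
        df = df.sort_values(["_rank"], kind="stable").drop(columns="_rank")

    conflicts = 0
    dup_mask = df.duplicated(subset="sample_id", keep="first")
    if dup_mask.any():
        for sid, grp in df[df["sample_id"].isin(df.loc[dup_mask, "sample_id"])].groupby("sample_id"):
            if grp[present].astype(str).drop_duplicates().shape[0] > 1:
                conflicts += 1
                logger.warning("conflicting duplicate outcomes for sample %s; keeping first by priority", sid)
    out = df[~dup_mask].reset_index(drop=True)
    report = {
        "n_input": int(len(samples)),
        "n_no_outcome": n_no_outcome,
        "n_duplicates_removed": int(dup_mask.sum()),
        "n_conflicts": conflicts,
        "n_output": int(len(out)),
    }
    return out, report


def _coerce_event(raw, coding):
    if coding:
        if str(raw) not in {str(k) for k in coding}:
            raise DataError(f"event value {raw!r} absent from event_coding")
        return int({str(k): v for k, v in coding.items()}[str(raw)])
    val = float(raw)
    if val not in (0.0, 1.0):
        raise DataError(f"event indicator {raw!r} is not 0/1 and no event_coding given")
    return int(val)


def standardize_outcomes(samples: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Standardize per-cohort raw outcome fields into the clinical schema.

    Each sample gains up to one record per endpoint (survival, metastasis);
    endpoints whose raw fields are missing for a sample are simply absent,
    the sample stays usable for the other endpoint.  Times are converted to
    months using the cohort's declared unit.
    """
    rows = []
    for cohort, grp in samples.groupby("cohort", sort=False):
        if cohort not in mapping:
            raise DataError(f"cohort {cohort!r} absent from the outcome mapping")
        rules = mapping[cohort]
        factor = _UNIT_TO_MONTHS.get(str(rules.get("unit", "months")).lower())
        if factor is None:
            raise ValidationError(f"unknown time unit {rules.get('unit')!r} for cohort {cohort!r}")
        for endpoint, fields in rules.get("endpoints", {}).items():
            if endpoint not in ("survival", "metastasis"):
                raise ValidationError(f"unknown endpoint {endpoint!r} in mapping for {cohort!r}")
            tcol, ecol = fields["time"], fields["event"]
            coding = fields.get("event_coding")
            for col in (tcol, ecol):
                if col not in grp.columns:
                    logger.warning("cohort %s: raw field %r missing; endpoint %s skipped",
                                   cohort, col, endpoint)
                    break
            else:
                sub = grp[grp[tcol].notna() & grp[ecol].notna()]
                for _, r in sub.iterrows():
                    time = float(r[tcol]) * factor
                    if time < 0:
                        raise ValidationError(
                            f"negative follow-up time for sample {r['sample_id']!r}"
                        )
                    rows.append(
                        {
                            "sample_id": r["sample_id"],
                            "endpoint": endpoint,
                            "time": time,
                            "event": _coerce_event(r[ecol], coding),
                            "stage": r.get("stage", np.nan),
                            "cohort": cohort,
                            "pub_year": int(r["pub_year"]) if "pub_year" in r else np.nan,
                            "provenance": f"{tcol}|{ecol}",
                        }
                    )
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def split_test_validation(clinical: pd.DataFrame, year_threshold: int = 2009):
    """Whole-cohort split: cohorts published ≤ threshold → test, later → validation."""
    if "pub_year" not in clinical.columns or clinical["pub_year"].isna().any():
        raise DataError("every cohort needs a pub_year for the test/validation split")
    test = clinical[clinical["pub_year"] <= year_threshold].reset_index(drop=True)
    validation = clinical[clinical["pub_year"] > year_threshold].reset_index(drop=True)
    if validation.empty:
        logger.warning("all cohorts published on or before %d: validation set is empty",
                       year_threshold)
    return test, validation


def subset_early_stage(clinical: pd.DataFrame, category: str = "T1") -> pd.DataFrame:
    """Keep samples of one TNM T category; missing-stage samples are excluded."""
    if "stage" not in clinical.columns:
        logger.warning("no stage column; early-stage subset is empty")
        return clinical.iloc[0:0].copy()
    known = clinical["stage"].notna()
    n_missing = int((~known).sum())
    if n_missing:
        logger.info("excluded %d samples without stage annotation", n_missing)
    out = clinical[known & (clinical["stage"].astype(str) == category)].reset_index(drop=True)
    if out.empty:
        logger.warning("no samples with stage %s", category)
    return out
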