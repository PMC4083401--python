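#!/usr/bin/env python
"""Harmonize heterogeneous per-cohort clinical annotations.

Each simulated cohort re-exports its outcomes under its own field names and
units (months vs years, coded vs numeric event flags), as real repositories
do.  This driver deduplicates the pooled raw table, standardizes everything
to (endpoint, time-in-months, 0/1 event) records with provenance, and splits
the meta-cohort into test and validation groups at the 2009 publication-year
boundary.

Reads results/data/clinical.tsv, writes results/clinical_{test,validation}.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coscore import io
from coscore.cohort import deduplicate, split_test_validation, standardize_outcomes

DATA = Path("results/data")
clinical = io.read_clinical(DATA / "clinical.tsv")

# re-export each cohort's records under cohort-specific raw field names
wide = clinical.pivot_table(
    index=["sample_id", "stage", "cohort", "pub_year"],
    columns="endpoint", values=["time", "event"], aggfunc="first",
).reset_index()
wide.columns = ["_".join(c).rstrip("_") if c[1] else c[0] for c in wide.columns]

raw_frames, mapping = [], {}
for cohort, grp in wide.groupby("cohort"):
    year = int(grp["pub_year"].iloc[0])
    if year <= 2009:  # older cohorts report years + coded vital status
        g = pd.DataFrame(
            {
                "sample_id": grp["sample_id"], "cohort": cohort, "pub_year": year,
                "stage": grp["stage"],
                "os_years": grp["time_survival"] / 12.0,
                "status": np.where(grp["event_survival"] == 1, "dead", "alive"),
                "mfs_years": grp["time_metastasis"] / 12.0,
                "met_status": np.where(grp["event_metastasis"] == 1, "met", "free"),
            }
        )
        mapping[cohort] = {
            "unit": "years",
            "endpoints": {
                "survival": {"time": "os_years", "event": "status",
                             "event_coding": {"dead": 1, "alive": 0}},
                "metastasis": {"time": "mfs_years", "event": "met_status",
                               "event_coding": {"met": 1, "free": 0}},
            },
        }
    else:
        g = pd.DataFrame(
            {
                "sample_id": grp["sample_id"], "cohort": cohort, "pub_year": year,
                "stage": grp["stage"],
                "os_months": grp["time_survival"], "os_event": grp["event_survival"],
                "mfs_months": grp["time_metastasis"], "met_event": grp["event_metastasis"],
            }
        )
        mapping[cohort] = {
            "unit": "months",
            "endpoints": {
                "survival": {"time": "os_months", "event": "os_event"},
                "metastasis": {"time": "mfs_months", "event": "met_event"},
            },
        }
    raw_frames.append(g)

raw = pd.concat(raw_frames, ignore_index=True)
outcome_fields = ["os_years", "status", "mfs_years", "met_status",
                  "os_months", "os_event", "mfs_months", "met_event"]
unique, report = deduplicate(raw, outcome_fields)
standardized = standardize_outcomes(unique, mapping)
test, validation = split_test_validation(standardized, 2009)

io.write_table(standardized, Path("results/clinical_harmonized.tsv"))
io.write_table(test, Path("results/clinical_test.tsv"))
io.write_table(validation, Path("results/clinical_validation.tsv"))
Path("results/harmonization_report.json").write_text(json.dumps(report, indent=2) + "\n")

print(f"deduplication report: {report}")
print(f"test: {test['sample_id'].nunique()} samples "
      f"({sorted(set(test['cohort']))}); "
      f"validation: {validation['sample_id'].nunique()} samples "
      f"({sorted(set(validation['cohort']))})")

# round-trip check: the standardized records must match the originals
merged = standardized.merge(clinical, on=["sample_id", "endpoint"], suffixes=("_std", "_orig"))
assert np.allclose(merged["time_std"], merged["time_orig"])
assert (merged["event_std"] == merged["event_orig"]).all()
print("round-trip check passed: standardized outcomes equal the generated ones")
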