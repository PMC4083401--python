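"""Clinical harmonization: dedup, outcome standardization, split, staging."""

import numpy as np
import pandas as pd
import pytest

from coscore.cohort import (
    deduplicate,
    split_test_validation,
    standardize_outcomes,
    subset_early_stage,
)
from coscore.errors import DataError, ValidationError

MAPPING = {
    "alpha": {
        "unit": "months",
        "endpoints": {
            "survival": {"time": "os_months", "event": "os_event"},
            "metastasis": {"time": "mfs_months", "event": "met_event"},
        },
    },
    "beta": {
        "unit": "years",
        "endpoints": {
            "survival": {
                "time": "os_years",
                "event": "status",
                "event_coding": {"dead": 1, "alive": 0},
            }
        },
    },
}

OUTCOME_FIELDS = ["os_months", "os_event", "mfs_months", "met_event", "os_years", "status"]


def raw_samples():
    rows = []
    for i in range(6):  # alpha cohort, 2006
        rows.append(
            {"sample_id": f"a{i}", "cohort": "alpha", "pub_year": 2006,
             "os_months": 20 + i, "os_event": i % 2,
             "mfs_months": 15 + i, "met_event": (i + 1) % 2, "stage": "T1" if i < 4 else "T2"}
        )
    for i in range(4):  # beta cohort, 2012, years + coded events
        rows.append(
            {"sample_id": f"b{i}", "cohort": "beta", "pub_year": 2012,
             "os_years": 2 + i, "status": "dead" if i % 2 else "alive", "stage": "T2"}
        )
    return pd.DataFrame(rows)


class TestDeduplicate:
    def test_counts_on_constructed_fixture(self):
        df = raw_samples()
        dup = pd.concat([df, df.iloc[[0, 3]]], ignore_index=True)  # 2 duplicates
        no_outcome = pd.DataFrame([{"sample_id": "z0", "cohort": "alpha", "pub_year": 2006}])
        full = pd.concat([dup, no_outcome], ignore_index=True)  # 13 rows in
        out, report = deduplicate(full, OUTCOME_FIELDS)
        assert report["n_input"] == 13
        assert report["n_duplicates_removed"] == 2
        assert report["n_no_outcome"] == 1
        assert len(out) == 10
        assert out["sample_id"].is_unique

    def test_conflicting_duplicates_keep_priority_cohort(self, caplog):
        df = pd.DataFrame(
            [
                {"sample_id": "s", "cohort": "beta", "pub_year": 2012, "os_years": 1, "status": "dead"},
                {"sample_id": "s", "cohort": "alpha", "pub_year": 2006, "os_months": 9, "os_event": 1},
            ]
        )
        with caplog.at_level("WARNING"):
            out, report = deduplicate(df, OUTCOME_FIELDS, cohort_priority=["alpha", "beta"])
        assert report["n_conflicts"] == 1
        assert out.iloc[0]["cohort"] == "alpha"

    def test_no_outcome_fields_present_rejected(self):
        with pytest.raises(DataError):
            deduplicate(pd.DataFrame({"sample_id": ["x"]}), OUTCOME_FIELDS)


class TestStandardizeOutcomes:
    def test_unit_conversion_and_coding(self):
        clin = standardize_outcomes(raw_samples(), MAPPING)
        b1 = clin[(clin.sample_id == "b1") & (clin.endpoint == "survival")].iloc[0]
        assert b1["time"] == 36.0  # 3 years -> months
        assert b1["event"] == 1  # "dead"
        assert b1["provenance"] == "os_years|status"

    def test_survival_only_sample_still_usable(self):
        clin = standardize_outcomes(raw_samples(), MAPPING)
        beta = clin[clin.cohort == "beta"]
        assert set(beta["endpoint"]) == {"survival"}
        alpha = clin[clin.cohort == "alpha"]
        assert set(alpha["endpoint"]) == {"survival", "metastasis"}

    def test_unknown_cohort_rejected(self):
        df = raw_samples().assign(cohort="gamma")
        with pytest.raises(DataError, match="gamma"):
            standardize_outcomes(df, MAPPING)

    def test_negative_time_rejected(self):
        df = raw_samples()
        df.loc[0, "os_months"] = -2
        with pytest.raises(ValidationError):
            standardize_outcomes(df, MAPPING)

    def test_standardized_endpoints_controlled(self):
        bad = {"alpha": {"unit": "months", "endpoints": {"relapse": {"time": "t", "event": "e"}}}}
        with pytest.raises(ValidationError):
            standardize_outcomes(raw_samples(), bad)


class TestSplitTestValidation:
    def three_cohorts(self):
        rows = []
        for cohort, year, n in (("c06", 2006, 40), ("c08", 2008, 30), ("c12", 2012, 20)):
            for i in range(n):
                rows.append({"sample_id": f"{cohort}_{i}", "endpoint": "survival",
                             "time": 10.0, "event": 1, "stage": "T1",
                             "cohort": cohort, "pub_year": year, "provenance": "t|e"})
        return pd.DataFrame(rows)

    def test_year_rule_split_70_20(self):
        test, validation = split_test_validation(self.three_cohorts(), 2009)
        assert len(test) == 70 and len(validation) == 20
        assert set(test["cohort"]) == {"c06", "c08"}
        assert len(test) + len(validation) == 90

    def test_all_cohorts_pre_threshold(self, caplog):
        df = self.three_cohorts()
        with caplog.at_level("WARNING"):
            test, validation = split_test_validation(df, 2020)
        assert validation.empty and len(test) == len(df)

    def test_assignment_independent_of_row_order(self):
        df = self.three_cohorts().sample(frac=1, random_state=0)
        test, validation = split_test_validation(df, 2009)
        assert set(test["cohort"]) == {"c06", "c08"} and set(validation["cohort"]) == {"c12"}

    def test_missing_pub_year_rejected(self):
        df = self.three_cohorts()
        df.loc[0, "pub_year"] = np.nan
        with pytest.raises(DataError):
            split_test_validation(df)


class TestSubsetEarlyStage:
    def fixture(self):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(9)], "endpoint": "survival",
             "time": 1.0, "event": 1,
             "stage": ["T1"] * 5 + ["T2"] * 3 + [np.nan]}
        )

    def test_t1_and_t2_counts(self):
        df = self.fixture()
        assert len(subset_early_stage(df, "T1")) == 5
        assert len(subset_early_stage(df, "T2")) == 3

    def test_missing_stage_excluded(self):
        out = subset_early_stage(self.fixture(), "T1")
        assert out["stage"].notna().all()

    def test_no_stage_annotation_at_all(self, caplog):
        df = self.fixture().drop(columns="stage")
        with caplog.at_level("WARNING"):
            out = subset_early_stage(df, "T1")
        assert out.empty
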