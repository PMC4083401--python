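"""The permutation/subsampling null and the Clinical Outcome score."""

import numpy as np
import pytest
from scipy import stats

from coscore import ScoreConfig, compute_co, evaluate_dataset, evaluate_feature
from coscore.errors import DataError, UnscorableError, ValidationError
from coscore.score import feature_seed, permutation_null


@pytest.fixture(scope="module")
def outcome_arrays(null_cohort):
    clin = null_cohort.clinical.set_index("sample_id").loc[null_cohort.expression.index]
    return (
        null_cohort.expression,
        clin["time"].to_numpy(float),
        clin["event"].to_numpy(float),
    )


class TestComputeCo:
    def test_direct_count(self):
        assert compute_co(0.03, [0.01, 0.02, 0.20, 0.80]) == 0.5

    def test_extreme_case_gives_zero(self):
        assert compute_co(1e-8, [0.1, 0.2, 0.3]) == 0.0

    def test_empty_null_rejected(self):
        with pytest.raises(UnscorableError):
            compute_co(0.5, [])

    def test_null_self_consistency(self, rng):
        # P_true drawn from the same distribution as P* -> CO ~ 0.5 on average
        cos = [compute_co(rng.random(), rng.random(400)) for _ in range(300)]
        assert np.mean(cos) == pytest.approx(0.5, abs=0.05)


class TestScoreConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"n_repetitions": 0}, {"removal_fraction": 1.0},
                   {"removal_fraction": -0.1}, {"min_cluster_size": 0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ScoreConfig(**kwargs)


class TestPermutationNull:
    def test_deterministic_given_seed(self, outcome_arrays):
        expr, t, e = outcome_arrays
        labels = np.array(["UP", "DOWN"] * (t.size // 2))
        cfg = ScoreConfig(n_repetitions=50, seed=9)
        a = permutation_null(t, e, labels, cfg)
        b = permutation_null(t, e, labels, cfg)
        np.testing.assert_array_equal(a, b)

    def test_single_repetition_reproducible(self, outcome_arrays):
        _, t, e = outcome_arrays
        labels = np.array(["UP", "DOWN"] * (t.size // 2))
        cfg = ScoreConfig(n_repetitions=1, seed=5)
        assert permutation_null(t, e, labels, cfg).size == 1
        assert permutation_null(t, e, labels, cfg) == permutation_null(t, e, labels, cfg)

    def test_calibrated_tail_without_removal(self, outcome_arrays, null_cohort):
        """With labels independent of outcome, fraction(P* <= 0.05) sits at
        0.05 within 3 binomial standard errors."""
        expr, t, e = outcome_arrays
        from coscore import kmeans_dichotomize

        labels = kmeans_dichotomize(expr.iloc[:, 0].to_numpy(), "f").labels
        cfg = ScoreConfig(n_repetitions=2000, removal_fraction=0.0, seed=17)
        ps = permutation_null(t, e, labels, cfg)
        band = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(np.mean(ps <= 0.05) - 0.05) <= band

    def test_degenerate_repetitions_dropped(self, rng):
        # one UP sample among ten with heavy removal: some repetitions lose
        # the whole UP group and must be dropped, not imputed
        t = rng.exponential(5, 10)
        e = np.ones(10)
        labels = np.array(["UP"] + ["DOWN"] * 9)
        cfg = ScoreConfig(n_repetitions=400, removal_fraction=0.3, seed=0)
        ps = permutation_null(t, e, labels, cfg)
        assert 0 < ps.size < 400

    def test_iid_relabel_mode(self, outcome_arrays):
        _, t, e = outcome_arrays
        labels = np.array(["UP", "DOWN"] * (t.size // 2))
        cfg = ScoreConfig(n_repetitions=100, seed=3, iid_relabel=True)
        assert permutation_null(t, e, labels, cfg).size <= 100


class TestEvaluateFeature:
    def test_true_target_scores_low(self, signal_cohort):
        clin = signal_cohort.clinical
        surv = clin[clin.endpoint == "survival"].set_index("sample_id")
        surv = surv.loc[signal_cohort.expression.index]
        cfg = ScoreConfig(n_repetitions=500, seed=1)
        res = evaluate_feature(
            signal_cohort.expression["feat_0000"].to_numpy(),
            surv["time"].to_numpy(), surv["event"].to_numpy(),
            cfg, feature_id="feat_0000",
        )
        assert res.co < 0.05
        assert res.lambda_up > res.lambda_down

    def test_affine_transform_leaves_co_unchanged(self, signal_cohort):
        clin = signal_cohort.clinical
        surv = clin[clin.endpoint == "survival"].set_index("sample_id")
        surv = surv.loc[signal_cohort.expression.index]
        cfg = ScoreConfig(n_repetitions=200, seed=1)
        t, e = surv["time"].to_numpy(), surv["event"].to_numpy()
        v = signal_cohort.expression["feat_0003"].to_numpy()
        base = evaluate_feature(v, t, e, cfg, feature_id="feat_0003")
        trans = evaluate_feature(3.0 * v + 7.0, t, e, cfg, feature_id="feat_0003")
        assert trans.co == base.co
        assert trans.p_true == pytest.approx(base.p_true)

    def test_per_subsample_p_true_mode_runs(self, signal_cohort):
        clin = signal_cohort.clinical
        surv = clin[clin.endpoint == "survival"].set_index("sample_id")
        surv = surv.loc[signal_cohort.expression.index]
        cfg = ScoreConfig(n_repetitions=100, seed=2, per_subsample_p_true=True)
        res = evaluate_feature(
            signal_cohort.expression["feat_0000"].to_numpy(),
            surv["time"].to_numpy(), surv["event"].to_numpy(), cfg, "feat_0000",
        )
        assert 0.0 <= res.co <= 1.0

    def test_feature_seed_is_order_free_and_31_bit(self):
        s1 = feature_seed(7, "featA", "survival")
        assert s1 == feature_seed(7, "featA", "survival")
        assert s1 != feature_seed(7, "featA", "metastasis")
        assert 0 <= s1 < 2**31


class TestEvaluateDataset:
    def test_true_targets_rank_top_and_results_deterministic(self, signal_cohort):
        cfg = ScoreConfig(n_repetitions=300, seed=4)
        tab = evaluate_dataset(
            signal_cohort.expression, signal_cohort.clinical, cfg,
            endpoints=["survival"],
        )
        truth = set(signal_cohort.truth.loc[signal_cohort.truth.is_true_target, "feature_id"])
        assert set(tab.head(2)["feature_id"]) == truth
        again = evaluate_dataset(
            signal_cohort.expression, signal_cohort.clinical, cfg,
            endpoints=["survival"],
        )
        assert tab.equals(again)
        assert tab["co"].between(0, 1).all()

    def test_constant_feature_skipped_with_reason(self, null_cohort):
        expr = null_cohort.expression.iloc[:, :3].copy()
        expr["flat"] = 1.0
        cfg = ScoreConfig(n_repetitions=20, seed=0)
        tab = evaluate_dataset(expr, null_cohort.clinical, cfg)
        assert "flat" not in set(tab["feature_id"])
        skipped = tab.attrs["skipped"]
        assert (skipped["feature_id"] == "flat").any()
        assert skipped.loc[skipped.feature_id == "flat", "reason"].str.contains("degenerate").all()

    def test_stage_filter_without_matching_samples_errors(self, null_cohort):
        cfg = ScoreConfig(n_repetitions=10, seed=0)
        with pytest.raises(DataError):
            evaluate_dataset(null_cohort.expression, null_cohort.clinical, cfg,
                             stage_filter="T4")

    def test_no_overlapping_samples_errors(self, null_cohort):
        expr = null_cohort.expression.copy()
        expr.index = ["x" + i for i in expr.index]
        with pytest.raises(DataError):
            evaluate_dataset(expr, null_cohort.clinical, ScoreConfig(n_repetitions=5))


def test_mean_co_non_increasing_in_hazard_ratio():
    """Monotone power: stronger true hazard ratios push CO down.

    Averaged over cohorts drawn with common seeds per hazard ratio; the
    common seeds couple the event-time draws across the grid, so the mean is
    stable enough at small replicate counts."""
    from coscore import SimulationConfig, generate_cohort

    means = []
    for hr in (1.0, 1.5, 2.0, 4.0):
        cos = []
        for seed in range(90, 102):
            cfg = SimulationConfig(
                n_samples=250, n_features=4, frac_true=0.5, hazard_ratio=hr,
                mixture_delta=3.0, seed=seed, endpoint_types=("survival",),
            )
            data = generate_cohort(cfg)
            tab = evaluate_dataset(data.expression, data.clinical,
                                   ScoreConfig(n_repetitions=200, seed=7))
            truth = set(data.truth.loc[data.truth.is_true_target, "feature_id"])
            cos.extend(tab[tab.feature_id.isin(truth)]["co"])
        means.append(np.mean(cos))
    assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
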