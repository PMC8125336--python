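"""Feature-level cohort sampling, LESS generation and signal recipes."""

import numpy as np
import pytest
from scipy import stats

from aclrisk import synth
from aclrisk.features import FEATURE_NAMES


class TestGroupModels:
    def test_default_correlation_is_psd_unit_diagonal(self):
        corr = synth.default_correlation()
        assert np.allclose(np.diag(corr), 1.0)
        assert np.linalg.eigvalsh(corr).min() > -1e-9

    def test_non_psd_correlation_rejected(self):
        corr = synth.default_correlation()
        corr[0, 1] = corr[1, 0] = -0.999
        corr[0, 2] = corr[2, 0] = 0.999
        corr[1, 2] = corr[2, 1] = 0.999
        with pytest.raises(ValueError, match="positive semi-definite"):
            synth.GroupFeatureModel("R", synth._R_MEAN, synth._R_SD, corr)

    def test_negative_sd_rejected(self):
        sd = np.array(synth._R_SD).copy()
        sd[0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            synth.GroupFeatureModel("R", synth._R_MEAN, sd)


class TestFeatureCohort:
    def test_shape_counts_and_reproducibility(self):
        c1 = synth.sample_feature_cohort(26, 13, seed=1)
        c2 = synth.sample_feature_cohort(26, 13, seed=1)
        assert len(c1.features) == 39
        assert (c1.labels == "NR").sum() == 26
        assert (c1.labels == "R").sum() == 13
        # fixed seed => bit-identical cohort
        assert np.array_equal(c1.feature_matrix, c2.feature_matrix)
        assert all(
            np.array_equal(a.items, b.items)
            for a, b in zip(c1.less_records, c2.less_records)
        )

    def test_group_mean_within_standard_errors(self):
        c = synth.sample_feature_cohort(26, 13, seed=1)
        ea = c.features.loc[c.labels == "R", "mCMJ_EA"]
        se = 0.2 / np.sqrt(13)
        assert abs(ea.mean() - 1.5) < 3 * se

    def test_degenerate_sd_reproduces_means_exactly(self):
        models = {
            "NR": synth.GroupFeatureModel(
                "NR", synth._NR_MEAN, np.zeros(13), synth.default_correlation()
            ),
            "R": synth.GroupFeatureModel(
                "R", synth._R_MEAN, np.zeros(13), synth.default_correlation()
            ),
        }
        c = synth.sample_feature_cohort(1, 1, models, seed=9)
        assert np.allclose(c.feature_matrix[0], synth._NR_MEAN)
        assert np.allclose(c.feature_matrix[1], synth._R_MEAN)

    def test_moments_converge_to_model_parameters(self):
        """Monte-Carlo check of the sampled SDs against the generator's own
        parameters (5% tolerance at n = 4000 per group)."""
        c = synth.sample_feature_cohort(4000, 4000, seed=7)
        X = c.feature_matrix
        for grp, sd in (("NR", synth._NR_SD), ("R", synth._R_SD)):
            sds = X[c.labels == grp].std(axis=0, ddof=1)
            rel = np.abs(sds - sd) / np.maximum(sd, 1e-9)
            assert rel.max() < 0.05

    def test_all_rows_nonnegative(self):
        c = synth.sample_feature_cohort(500, 500, seed=3)
        assert (c.feature_matrix >= 0).all()

    def test_cohort_dir_round_trip(self, tmp_path):
        c = synth.sample_feature_cohort(6, 4, seed=2)
        c.to_dir(tmp_path / "cohort")
        assert (tmp_path / "cohort" / "features.csv").exists()
        assert (tmp_path / "cohort" / "labels.json").exists()
        assert (tmp_path / "cohort" / "less_records.json").exists()


class TestLessGeneration:
    def test_all_nr_zero_mean_gives_all_zero_items(self):
        recs = synth.generate_less_records(
            ["NR"] * 10, target_means=(0.0, 7.5), seed=1
        )
        for r in recs:
            assert np.all(r.items == 0)
            assert r.median_score == 0

    def test_medians_respect_labels(self):
        labels = ["NR"] * 26 + ["R"] * 13
        ea = np.concatenate([np.full(26, 0.7), np.full(13, 1.5)])
        recs = synth.generate_less_records(
            labels, target_rho=0.88, ea=ea, seed=3
        )
        for r, lab in zip(recs, labels):
            if lab == "NR":
                assert r.median_score <= 5
            else:
                assert r.median_score >= 6

    def test_item_ranges_and_scale_maximum(self):
        recs = synth.generate_less_records(
            ["R"] * 20, target_means=(3.5, 19.0), seed=4
        )
        for r in recs:
            assert np.all(r.items[:, :15] <= 1)
            assert np.all(r.items[:, 15:] <= 2)
            assert np.all(r.items >= 0)
            assert max(r.per_jump_scores) <= 19

    def test_unreachable_mean_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            synth.generate_less_records(["NR"] * 5, target_means=(7.0, 7.5), seed=0)
        with pytest.raises(ValueError, match="unreachable"):
            synth.generate_less_records(["R"] * 5, target_means=(3.5, 4.0), seed=0)

    def test_rank_correlation_recovery(self):
        c = synth.sample_feature_cohort(200, 100, seed=5, less_target_rho=0.88)
        ea = c.features["mCMJ_EA"].to_numpy()
        med = np.array([r.median_score for r in c.less_records])
        rho = stats.spearmanr(ea, med).statistic
        assert abs(rho - 0.88) < 0.1


class TestSignalRecipe:
    def test_validation_errors(self):
        with pytest.raises(ValueError, match="Ts"):
            synth.SignalRecipe(task="mCMJ", ts=-0.1)
        with pytest.raises(ValueError, match="T_DP"):
            synth.SignalRecipe(task="SLS", t_dp=0.0, theta_ymax=10.0)
        with pytest.raises(ValueError, match="EA"):
            synth.SignalRecipe(task="mCMJ", ts=0.3, ea=-1.0)

    def test_infeasible_pl_projected_within_bounds(self):
        r = synth.SignalRecipe(
            task="mCMJ", ts=0.3, pl=2.9, pl_ap=1.6, pl_ml=1.1, ea=0.7
        )
        lo = np.hypot(1.6, 1.1)
        assert lo <= r.target_features["mCMJ_PL"] <= 2.7
        assert r.requested["mCMJ_PL"] == 2.9

    def test_grossly_infeasible_pl_raises(self):
        with pytest.raises(ValueError, match="PL target"):
            synth.SignalRecipe(
                task="mCMJ", ts=0.3, pl=50.0, pl_ap=1.0, pl_ml=1.0, ea=0.1
            )

    def test_trial_determinism(self):
        kw = dict(task="mCMJ", ts=0.3, pl=2.0, pl_ap=1.2, pl_ml=1.0,
                  ea=0.5, rms_z=90.0, rms_xy=60.0, seed=8)
        t1, led1 = synth.synthesize_jump_trial(synth.SignalRecipe(**kw))
        t2, led2 = synth.synthesize_jump_trial(synth.SignalRecipe(**kw))
        assert np.array_equal(t1.accel, t2.accel)
        assert np.array_equal(t1.gyro, t2.gyro)
        assert np.array_equal(led1.on, led2.on)

    def test_from_features_round_trip(self, nr_means):
        r = synth.SignalRecipe.from_features("mCMJ", nr_means, seed=1)
        assert r.target_features["mCMJ_Ts"] == nr_means["mCMJ_Ts"]
        assert r.target_features["mCMJ_RMS_z"] == nr_means["mCMJ_RMS_z"]
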