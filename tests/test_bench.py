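"""Confusion-matrix metrics, fold construction and the classifier bench."""

from fractions import Fraction

import numpy as np
import pytest

from aclrisk import bench, synth
from aclrisk.bench import (
    ConfusionMatrix,
    accuracy,
    f1_score,
    g_index,
    goodness_category,
    run_bench,
    split_folds,
)


class TestMetricFormulas:
    def test_perfect_and_inverted(self):
        assert accuracy(ConfusionMatrix(26, 13, 0, 0)) == 1.0
        assert accuracy(ConfusionMatrix(0, 0, 26, 13)) == 0.0
        assert f1_score(ConfusionMatrix(26, 13, 0, 0)) == 1.0
        assert f1_score(ConfusionMatrix(0, 13, 0, 26)) == 0.0

    def test_hand_arithmetic(self):
        cm = ConfusionMatrix(20, 10, 6, 3)
        assert accuracy(cm) == pytest.approx(30 / 39)
        re, pr = Fraction(20, 23), Fraction(20, 26)
        assert f1_score(cm) == pytest.approx(float(2 * re * pr / (re + pr)))

    def test_g_examples(self):
        assert g_index(ConfusionMatrix(10, 10, 0, 0)) == 0.0
        # chance-level rates 0.5/0.5 sit at sqrt(0.5)
        assert g_index(ConfusionMatrix(5, 5, 5, 5)) == pytest.approx(np.sqrt(0.5))
        assert g_index(ConfusionMatrix(0, 0, 5, 5)) == pytest.approx(np.sqrt(2))

    def test_exhaustive_small_matrices_against_fraction_oracle(self):
        """A, F1, G agree with exact rational arithmetic on every confusion
        matrix of total <= 12 (the larger sweep runs in acceptance)."""
        total = 0
        for tp in range(13):
            for tn in range(13 - tp):
                for fp in range(13 - tp - tn):
                    for fn in range(13 - tp - tn - fp):
                        if tp + tn + fp + fn == 0:
                            continue
                        cm = ConfusionMatrix(tp, tn, fp, fn)
                        acc = Fraction(tp + tn, tp + tn + fp + fn)
                        assert accuracy(cm) == pytest.approx(float(acc))
                        if tp == 0:
                            assert f1_score(cm) == 0.0
                        else:
                            re = Fraction(tp, tp + fn)
                            pr = Fraction(tp, tp + fp)
                            assert f1_score(cm) == pytest.approx(
                                float(2 * re * pr / (re + pr))
                            )
                        if tp + fn > 0 and tn + fp > 0:
                            sens = Fraction(tp, tp + fn)
                            spec = Fraction(tn, tn + fp)
                            exp = float(
                                ((1 - sens) ** 2 + (1 - spec) ** 2) ** Fraction(1)
                            ) ** 0.5
                            assert g_index(cm) == pytest.approx(exp)
                        total += 1
        assert total > 1000

    def test_fp_fn_swap_symmetry(self):
        # F1 = 2TP / (2TP + FP + FN) is symmetric in FP/FN at fixed TP; the
        # asymmetry appears when the positive-class role is swapped
        a, b = ConfusionMatrix(20, 10, 6, 3), ConfusionMatrix(20, 10, 3, 6)
        assert accuracy(a) == accuracy(b)
        assert f1_score(a) == f1_score(b)
        swapped_roles = ConfusionMatrix(10, 20, 3, 6)
        assert f1_score(a) != f1_score(swapped_roles)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestGoodnessBands:
    @pytest.mark.parametrize(
        "g,cat",
        [(0.08, "optimum"), (0.25, "optimum"), (0.4, "good"), (0.70, "good"),
         (np.sqrt(0.5), "random"), (0.9, "bad"), (np.sqrt(2), "bad")],
    )
    def test_bands(self, g, cat):
        assert goodness_category(g) == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            goodness_category(1.6)


class TestSplitFolds:
    def test_grouped_ninefold_partition(self):
        folds = split_folds(39, "grouped-9fold", seed=0)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {4, 5}
        union = np.concatenate(folds)
        assert len(union) == 39 and len(np.unique(union)) == 39

    def test_grouped_stratified_keeps_classes_spread(self):
        labels = np.array(["NR"] * 26 + ["R"] * 13)
        folds = split_folds(39, "grouped-9fold", seed=1, labels=labels)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {4, 5}
        assert sorted(np.concatenate(folds)) == list(range(39))

    def test_paper_literal_thirty_nine_split(self):
        folds = split_folds(39, "random-holdout", seed=2)
        assert len(folds) == 9
        for f in folds:
            assert len(f) == 9 and len(np.unique(f)) == 9  # train size 30

    def test_nine_athletes_is_leave_one_out(self):
        folds = split_folds(9, "grouped-9fold", seed=3)
        assert all(len(f) == 1 for f in folds)

    def test_too_few_athletes(self):
        with pytest.raises(ValueError):
            split_folds(5, "grouped-9fold")


class TestRunBench:
    def _toy(self, n_per_class=18, gap=10.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.normal(-gap, 0.1, size=(n_per_class, 2)),
                rng.normal(gap, 0.1, size=(n_per_class, 2)),
            ]
        )
        y = np.array(["NR"] * n_per_class + ["R"] * n_per_class)
        return X, y

    def test_separable_toy_data_all_nine_perfect(self):
        X, y = self._toy()
        res = run_bench(X, y, seed=0)
        for variant, entry in res.entries.items():
            assert entry["accuracy"] == 1.0, variant
            assert entry["category"] == "optimum", variant

    def test_confusion_counts_reproducible(self):
        c = synth.sample_feature_cohort(26, 13, seed=11)
        r1 = run_bench(c.features, c.labels, seed=4)
        r2 = run_bench(c.features, c.labels, seed=4)
        assert r1.entries == r2.entries

    def test_counts_sum_to_cohort_size(self):
        c = synth.sample_feature_cohort(26, 13, seed=11)
        res = run_bench(c.features, c.labels, seed=4)
        for entry in res.entries.values():
            assert sum(entry["confusion"].values()) == 39

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="two classes"):
            run_bench(X, ["NR"] * 20, seed=0)

    def test_standardization_uses_training_statistics_only(self, monkeypatch):
        """The scaler must be fitted on training-fold rows only: spy on every
        StandardScaler.fit call and check no test-fold row sneaks in."""
        from sklearn.preprocessing import StandardScaler

        X, y = self._toy()
        fitted_sizes = []
        orig_fit = StandardScaler.fit

        def spy(self, data, *a, **kw):
            fitted_sizes.append(np.asarray(data).shape[0])
            return orig_fit(self, data, *a, **kw)

        monkeypatch.setattr(StandardScaler, "fit", spy)
        run_bench(X, y, configs=("l-SVM",), seed=1)
        n = len(X)
        assert len(fitted_sizes) == 9
        # every fit saw strictly fewer rows than the cohort (its train fold)
        assert all(sz == n - n // 9 or sz == n - (n // 9 + 1) for sz in fitted_sizes)

    def test_per_fold_pooling_option(self):
        X, y = self._toy()
        res = run_bench(X, y, configs=("l-SVM",), seed=0, pooling="per-fold")
        assert res.entries["l-SVM"]["accuracy"] == 1.0
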