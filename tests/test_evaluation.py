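import numpy as np
import pytest

import sixmanet.evaluation as ev
from sixmanet import (
    ConfusionCounts,
    DnaSequence,
    LabeledDataset,
    TrainConfig,
    baseline_auprc,
    confusion,
    kfold_cv,
    metrics,
    pr_curve,
    roc_auc,
    subsample_ratio,
)
from sklearn.model_selection import StratifiedKFold

from _oracles import (
    oracle_auc_all_pairs,
    oracle_average_precision,
    oracle_metrics,
)


# ---------------------------------------------------------------------------
# confusion + scalar metrics

class TestConfusionAndMetrics:
    def test_confusion_by_definition(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
        assert c.total == 4

    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_worked_example(self):
        """TP=50 TN=40 FP=10 FN=0 -> Acc .9, Sn 1, Sp .8, MCC sqrt(2/3)."""
        r = metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        assert r.acc == pytest.approx(0.9)
        assert r.sn == pytest.approx(1.0)
        assert r.sp == pytest.approx(0.8)
        assert r.mcc == pytest.approx(np.sqrt(2 / 3), abs=1e-12)

    def test_symmetric_no_skill(self):
        r = metrics(ConfusionCounts(25, 25, 25, 25))
        assert (r.acc, r.mcc) == (0.5, 0.0)

    def test_perfect_balanced(self):
        r = metrics(ConfusionCounts(tp=30, tn=30, fp=0, fn=0))
        assert (r.acc, r.sn, r.sp, r.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_against_oracle_on_random_tables(self, rng):
        """1,000 random confusion tables agree with the independent oracle
        to 1e-12, including degenerate zero-denominator cases."""
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + tn + fp + fn == 0:
                continue
            r = metrics(ConfusionCounts(tp, tn, fp, fn))
            exp = oracle_metrics(tp, tn, fp, fn)
            for got, want in zip((r.acc, r.sn, r.sp, r.mcc), exp):
                assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# threshold-free metrics

class TestRocAuc:
    def test_all_ties_is_half(self):
        assert roc_auc([1, 0, 1, 0], [0.3] * 4) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self, rng):
        """Trapezoidal AUC equals the Mann-Whitney statistic exactly, with
        tied scores (coarse grid) included."""
        for n in (10, 50, 200):
            for _ in range(20):
                y = rng.integers(0, 2, n)
                if y.sum() in (0, n):
                    continue
                s = rng.integers(0, 8, n) / 7.0  # coarse grid forces ties
                assert roc_auc(y, s) == pytest.approx(
                    oracle_auc_all_pairs(y, s), abs=1e-12)


class TestPrCurve:
    def test_perfect_separation_area_one(self):
        assert pr_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]).area == pytest.approx(1.0)

    def test_worked_four_sample_instance(self):
        """y=[1,0,1,0], s=[.9,.8,.7,.1]: AP = .5*1 + .5*(2/3) = 5/6."""
        curve = pr_curve([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert curve.area == pytest.approx(5 / 6, abs=1e-12)
        assert curve.area == pytest.approx(
            oracle_average_precision([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.integers(0, 10, n) / 9.0
            assert pr_curve(y, s).area == pytest.approx(
                oracle_average_precision(y, s), abs=1e-12)

    def test_recall_non_decreasing_in_unit_interval(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        curve = pr_curve(y, s)
        assert np.all(np.diff(curve.recall) >= 0)
        assert curve.recall.min() >= 0 and curve.recall.max() <= 1
        assert np.all((curve.precision >= 0) & (curve.precision <= 1))

    def test_random_scorer_approaches_prevalence(self):
        """Uninformative scores yield AUPRC near the positive fraction."""
        rng = np.random.default_rng(42)
        y = np.zeros(5000, dtype=int)
        y[:750] = 1  # 15% positives
        areas = [pr_curve(y, rng.random(5000)).area for _ in range(20)]
        assert np.mean(areas) == pytest.approx(0.15, abs=0.01)


class TestBaselineAuprc:
    def test_fraction_of_positives(self):
        assert baseline_auprc([1] * 15 + [0] * 85) == pytest.approx(0.15)

    def test_balanced(self):
        assert baseline_auprc([0, 1] * 10) == 0.5

    def test_dataset_input(self):
        seq = DnaSequence("s", "A" * 41)
        ds = LabeledDataset([seq] * 4, [1, 0, 0, 0])
        assert baseline_auprc(ds) == 0.25


# ---------------------------------------------------------------------------
# imbalanced-ratio construction

def _dummy_dataset(n_pos, n_neg):
    seq = DnaSequence("s", "A" * 41)
    return LabeledDataset([seq] * (n_pos + n_neg),
                          [1] * n_pos + [0] * n_neg, name="d")


class TestSubsampleRatio:
    @pytest.mark.parametrize(
        "n_pos,n_neg,ratio,expected_pos",
        [
            (1966, 1966, 5, 393),
            (1966, 1966, 10, 196),
            (813, 813, 5, 162),
            (813, 813, 10, 81),
            (31873, 31873, 5, 6374),
            (31873, 31873, 10, 3187),
        ],
    )
    def test_benchmark_ratio_counts(self, n_pos, n_neg, ratio, expected_pos):
        """All negatives kept; positives downsampled to floor(n_neg/ratio)."""
        sub = subsample_ratio(_dummy_dataset(n_pos, n_neg), ratio, seed=0)
        assert sub.positive_count == expected_pos
        assert sub.negative_count == n_neg

    def test_ratio_one_is_identity_in_counts(self):
        sub = subsample_ratio(_dummy_dataset(100, 100), 1, seed=0)
        assert (sub.positive_count, sub.negative_count) == (100, 100)

    def test_reproducible_under_seed(self, separable_dataset):
        a = subsample_ratio(separable_dataset, 5, seed=3)
        b = subsample_ratio(separable_dataset, 5, seed=3)
        assert a.sequences == b.sequences and a.labels == b.labels

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            subsample_ratio(_dummy_dataset(5, 5), 10, seed=0)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            subsample_ratio(_dummy_dataset(5, 5), 0, seed=0)


# ---------------------------------------------------------------------------
# cross-validation

FAST_TRAIN = TrainConfig(max_epochs=25, patience=5, batch_size=64, seed=0)


class TestKFoldCV:
    def test_stratified_partition_arithmetic(self, separable_dataset):
        """Folds are disjoint, cover the data, and balance the classes."""
        y = np.asarray(separable_dataset.labels)
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        X = np.zeros((len(y), 1))
        seen = []
        for _, te in splitter.split(X, y):
            assert abs(y[te].mean() - y.mean()) < 1 / len(te) + 1e-9
            seen.append(set(te))
        assert set().union(*seen) == set(range(len(y)))
        assert sum(len(s) for s in seen) == len(y)

    def test_class_count_below_k_rejected(self):
        with pytest.raises(ValueError, match="class"):
            kfold_cv(_dummy_dataset(3, 50), k=5)

    def test_separable_fixture_learnable(self, separable_dataset):
        result = kfold_cv(separable_dataset, k=5, train_config=FAST_TRAIN, seed=0)
        assert result.mean["acc"] >= 0.95
        assert len(result.fold_reports) == 5
        assert all(c > 0 for c in result.fold_selected_counts)

    def test_mean_std_formatting(self, separable_dataset):
        result = kfold_cv(separable_dataset, k=5, train_config=FAST_TRAIN, seed=0)
        text = result.format_mean_std("acc")
        assert "±" in text and text.split("±")[0].count(".") == 1

    def test_no_test_fold_row_reaches_fitting(self, separable_dataset, monkeypatch):
        """Leakage guard: instrument selector fitting and network training
        and verify they only ever see the training rows of each fold."""
        from sixmanet.encoders import encode_dataset

        X_all, y_all = encode_dataset(separable_dataset)
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        expected_train_rows = [
            {X_all[i].tobytes() for i in tr}
            for tr, _ in splitter.split(X_all, y_all)
        ]
        expected_test_rows = [
            {X_all[i].tobytes() for i in te}
            for _, te in splitter.split(X_all, y_all)
        ]

        seen_fit, seen_train = [], []
        real_fit, real_train = ev.fit_selector, ev.train

        def spy_fit(X, y, **kw):
            seen_fit.append({row.tobytes() for row in np.asarray(X)})
            return real_fit(X, y, **kw)

        def spy_train(net, X, y, cfg, **kw):
            seen_train.append(len(np.asarray(X)))
            return real_train(net, X, y, cfg, **kw)

        monkeypatch.setattr(ev, "fit_selector", spy_fit)
        monkeypatch.setattr(ev, "train", spy_train)
        kfold_cv(separable_dataset, k=5, train_config=FAST_TRAIN, seed=0)

        assert len(seen_fit) == 5
        for fold, rows in enumerate(seen_fit):
            assert rows == expected_train_rows[fold]
            assert not rows & (expected_test_rows[fold] - expected_train_rows[fold])
        # the network sees exactly the selector's row count per fold
        assert seen_train == [len(r) for r in expected_train_rows]
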