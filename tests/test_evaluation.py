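"""Cross-validation machinery, F-score arithmetic, report structure."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from ssvepbench.evaluation import (
    ConfusionMatrix,
    evaluate,
    f_scores,
    loro_splits,
    per_class_table,
    sweep,
)
from ssvepbench.synthetic_data import NOISE_ONLY, SimulationConfig, generate_dataset


class TestSplits:
    def test_default_dataset_gives_twenty_folds(self):
        ds = generate_dataset(SimulationConfig(seed=0, duration_s=1.0))
        folds = loro_splits(ds)
        assert len(folds) == 20
        assert all(len(train) == 19 for train, _ in folds)

    def test_two_runs_two_folds(self, moderate_dataset):
        ds = generate_dataset(SimulationConfig(n_runs=2, duration_s=1.0, seed=0))
        assert len(loro_splits(ds)) == 2

    def test_test_runs_partition_all_runs(self, moderate_dataset):
        folds = loro_splits(moderate_dataset)
        tests = [test for _, test in folds]
        assert sorted(tests) == list(range(moderate_dataset.n_runs))
        for train, test in folds:
            assert test not in train
            assert sorted(train + [test]) == list(range(moderate_dataset.n_runs))


class TestFScores:
    def test_identity_confusion_is_perfect(self):
        conf = ConfusionMatrix(20 * np.eye(4, dtype=int), (6.0, 8.0, 9.0, 10.0))
        scores, macro = f_scores(conf)
        assert macro == 1.0
        assert all(s.precision == s.sensitivity == s.f_score == 1.0 for s in scores)

    def test_hand_arithmetic_example(self):
        # class 0: TP=8, FP=2, FN=2 -> Pr=Se=F=0.8
        counts = np.array([[8, 1, 1], [2, 8, 0], [0, 1, 9]])
        conf = ConfusionMatrix(counts, (6.0, 8.0, 9.0))
        scores, _ = f_scores(conf)
        assert scores[0].precision == pytest.approx(0.8)
        assert scores[0].sensitivity == pytest.approx(0.8)
        assert scores[0].f_score == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 10, (4, 4))
        counts[np.arange(4), np.arange(4)] += 1  # avoid fully degenerate classes
        conf = ConfusionMatrix(counts, (6.0, 8.0, 9.0, 10.0))
        scores, macro = f_scores(conf)
        y_true, y_pred = [], []
        for i in range(4):
            for j in range(4):
                y_true += [i] * counts[i, j]
                y_pred += [j] * counts[i, j]
        pr, se, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0
        )
        np.testing.assert_allclose([s.precision for s in scores], pr, atol=1e-12)
        np.testing.assert_allclose([s.sensitivity for s in scores], se, atol=1e-12)
        np.testing.assert_allclose([s.f_score for s in scores], f1, atol=1e-12)
        assert macro == pytest.approx(np.mean(f1), abs=1e-12)

    def test_degenerate_class_flagged_zero(self):
        counts = np.array([[5, 0], [3, 0]])  # class 1 never predicted nor hit
        scores, macro = f_scores(ConfusionMatrix(counts, (6.0, 8.0)))
        assert scores[1].f_score == 0.0
        assert scores[1].degenerate

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            f_scores(ConfusionMatrix(np.zeros((2, 2), dtype=int), (6.0, 8.0)))

    def test_macro_f_invariant_to_class_order(self, rng):
        counts = rng.integers(1, 10, (3, 3))
        _, macro = f_scores(ConfusionMatrix(counts, (6.0, 8.0, 9.0)))
        perm = [2, 0, 1]
        _, macro_p = f_scores(
            ConfusionMatrix(counts[np.ix_(perm, perm)], (9.0, 6.0, 8.0))
        )
        assert macro == pytest.approx(macro_p, abs=1e-12)


class TestEvaluate:
    def test_high_snr_macro_f_is_one(self, high_snr_dataset):
        rep = evaluate(high_snr_dataset, "cca", 2.0)
        assert rep.macro_f == 1.0
        assert rep.confusion.total == len(high_snr_dataset.trials)

    def test_noise_only_near_chance(self):
        ds = generate_dataset(
            SimulationConfig(n_runs=10, duration_s=1.0, snr_db=NOISE_ONLY, seed=21)
        )
        rep = evaluate(ds, "cca", 1.0)
        # 40 predictions at chance 0.25; generous binomial band
        assert 0.025 <= rep.accuracy <= 0.55

    def test_window_exceeding_trial_rejected(self, high_snr_dataset):
        with pytest.raises(ValueError, match="exceeds trial duration"):
            evaluate(high_snr_dataset, "cca", 5.0)

    def test_report_records_match_confusion(self, high_snr_dataset):
        rep = evaluate(high_snr_dataset, "msetcca", 1.0)
        assert len(rep.records) == rep.confusion.total
        row_sums = rep.confusion.counts.sum(axis=1)
        np.testing.assert_array_equal(row_sums, [high_snr_dataset.n_runs] * 4)

    def test_repeated_evaluation_identical(self, moderate_dataset):
        a = evaluate(moderate_dataset, "l1mcca", 1.0, seed=5)
        b = evaluate(moderate_dataset, "l1mcca", 1.0, seed=5)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)
        assert a.records == b.records

    def test_montage_condition_labelled(self, high_snr_dataset):
        rep = evaluate(high_snr_dataset, "cca", 1.0, montage_spec="Oz-Pz,O1-P7")
        assert rep.montage == "Oz-Pz,O1-P7"
        assert rep.macro_f == 1.0

    def test_report_roundtrip_via_dict(self, high_snr_dataset):
        from ssvepbench.evaluation import EvaluationReport

        rep = evaluate(high_snr_dataset, "cfa", 1.0)
        back = EvaluationReport.from_dict(rep.to_dict())
        assert back.macro_f == rep.macro_f
        assert back.records == rep.records
        np.testing.assert_array_equal(back.confusion.counts, rep.confusion.counts)

    def test_summary_table_columns(self, high_snr_dataset):
        rep = evaluate(high_snr_dataset, "cca", 1.0)
        df = rep.summary()
        assert list(df.columns) == [
            "class_hz", "TP", "FP", "FN", "precision", "sensitivity", "f_score",
        ]
        assert len(df) == 4


def test_sweep_long_format_row_count(high_snr_dataset):
    table, reports = sweep(high_snr_dataset, ["cca", "cfa"], [0.5, 1.0], [None, "Oz-Pz"])
    assert len(table) == 2 * 2 * 2
    assert list(table.columns) == ["montage", "decoder", "window_s", "macro_f"]
    per_class = per_class_table(reports)
    assert len(per_class) == len(table) * 4
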