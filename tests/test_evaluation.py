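"""Metrics schema, cross-validation contracts and the online tally loop."""

import numpy as np
import pandas as pd
import pytest

from neurodrive.evaluation import (MetricsReport, TallyTable, compute_metrics,
                                   kfold_cv, make_psd_decoder, mean_report,
                                   overall_accuracy_pct, replay_online,
                                   truth_per_chunk)
from neurodrive.io import STATES


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(["focused", "visual", "auditory", "cognitive"] * 5)
        r = compute_metrics(y, y)
        assert r.accuracy_pct == 100.0
        assert r.kappa == pytest.approx(1.0)
        assert all(v == 1.0 for v in r.precision.values())
        assert all(v == 1.0 for v in r.recall.values())

    def test_constant_predictor_kappa_zero(self):
        y_true = np.array(["focused"] * 10 + ["visual"] * 10)
        y_pred = np.array(["focused"] * 20)
        assert compute_metrics(y_true, y_pred).kappa == pytest.approx(0.0)

    def test_hand_built_confusion_matrix(self):
        """4x4 confusion with known counts; expectations computed by hand
        from the definitions (not via sklearn)."""
        # rows true, cols predicted, order V A C F
        cm = np.array([[8, 1, 1, 0],
                       [2, 6, 1, 1],
                       [0, 1, 9, 0],
                       [1, 0, 2, 7]])
        classes = ["visual", "auditory", "cognitive", "focused"]
        y_true, y_pred = [], []
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                y_true += [ci] * cm[i, j]
                y_pred += [cj] * cm[i, j]
        r = compute_metrics(y_true, y_pred, classes)
        n = cm.sum()
        po = cm.trace() / n                       # 30/40
        pe = sum(cm[i].sum() * cm[:, i].sum() for i in range(4)) / n ** 2
        assert r.accuracy_pct == pytest.approx(100 * po)
        assert r.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        assert r.precision["visual"] == pytest.approx(8 / 11)
        assert r.recall["auditory"] == pytest.approx(6 / 10)
        f1s = []
        for i in range(4):
            p = cm[i, i] / cm[:, i].sum()
            q = cm[i, i] / cm[i].sum()
            f1s.append(2 * p * q / (p + q))
        assert r.macro_f1 == pytest.approx(np.mean(f1s), abs=1e-12)
        np.testing.assert_array_equal(r.confusion, cm)

    def test_macro_f1_equals_mean_of_per_class_f1(self, rng):
        y_true = rng.choice(STATES, size=200)
        y_pred = rng.choice(STATES, size=200)
        r = compute_metrics(y_true, y_pred, list(STATES))
        from sklearn.metrics import f1_score

        per_class = f1_score(y_true, y_pred, labels=list(STATES), average=None,
                             zero_division=0)
        assert r.macro_f1 == pytest.approx(per_class.mean(), abs=1e-10)

    def test_relabeling_permutes_rows_not_accuracy(self, rng):
        y_true = rng.choice(["visual", "auditory"], size=100)
        y_pred = rng.choice(["visual", "auditory"], size=100)
        r1 = compute_metrics(y_true, y_pred, ["visual", "auditory"])
        swap = {"visual": "auditory", "auditory": "visual"}
        r2 = compute_metrics([swap[v] for v in y_true], [swap[v] for v in y_pred],
                             ["visual", "auditory"])
        assert r1.accuracy_pct == pytest.approx(r2.accuracy_pct)
        assert r1.kappa == pytest.approx(r2.kappa)
        assert r1.precision["visual"] == pytest.approx(r2.precision["auditory"])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])

    def test_confusion_row_sums_equal_true_counts(self, rng):
        y_true = rng.choice(STATES, size=120)
        y_pred = rng.choice(STATES, size=120)
        r = compute_metrics(y_true, y_pred, list(STATES))
        for i, c in enumerate(r.classes):
            assert r.confusion[i].sum() == np.sum(y_true == c)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((100, 5))
    y = np.array((["focused"] * 50) + (["visual"] * 50))
    X[y == "visual"] += 2.0
    return X, y


class TestKFold:
    def test_folds_stratified_and_partition(self, toy_data):
        from sklearn.model_selection import StratifiedKFold

        X, y = toy_data
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for tr, te in cv.split(X, y):
            assert abs(np.sum(y[te] == "focused") - np.sum(y[te] == "visual")) <= 1
            seen.append(te)
        all_idx = np.concatenate(seen)
        assert sorted(all_idx) == list(range(100))

    def test_kfold_cv_runs_and_aggregates(self, toy_data):
        from sklearn.linear_model import LogisticRegression

        X, y = toy_data
        reports, mean_r = kfold_cv(lambda: LogisticRegression(), X, y, k=5, seed=0)
        assert len(reports) == 5
        assert sum(r.n_samples for r in reports) == 100 == mean_r.n_samples
        assert mean_r.accuracy_pct == pytest.approx(
            np.mean([r.accuracy_pct for r in reports]))

    def test_small_class_rejected(self, toy_data):
        X, y = toy_data
        y2 = y.copy()
        y2[:97] = "focused"
        with pytest.raises(ValueError, match="samples"):
            kfold_cv(lambda: None, X, y2, k=5)

    def test_mean_of_subject_accuracies(self):
        """Averaging per-subject reports reproduces the arithmetic mean of
        their accuracies."""
        accs = [69.42, 76.57, 86.93, 78.36, 70.70, 78.65, 71.26, 80.32, 79.53, 85.19]
        reports = [MetricsReport(a, 0.7, 0.7, {"visual": 1}, {"visual": 1},
                                 np.zeros((1, 1), dtype=int), ["visual"], 100)
                   for a in accs]
        assert mean_report(reports).accuracy_pct == pytest.approx(np.mean(accs))


class TestTally:
    def test_counts_within_bounds_and_overall(self):
        t = TallyTable.from_counts({"visual": (65, 52), "auditory": (150, 72),
                                    "cognitive": (100, 69), "focused": (608, 486)})
        assert (t.table["C"] <= t.table["T"]).all()
        assert t.overall_accuracy == pytest.approx(679 / 923)

    def test_printed_counts_reproduce_percentage(self):
        counts = {"visual": (65, 52), "auditory": (150, 72),
                  "cognitive": (100, 69), "focused": (608, 486)}
        assert overall_accuracy_pct(counts) == pytest.approx(73.56, abs=0.005)

    def test_from_predictions_bookkeeping(self):
        y_true = ["visual"] * 5 + ["auditory"] * 15 + ["cognitive"] * 10
        y_pred = ["visual"] * 4 + ["focused"] + ["auditory"] * 15 + ["focused"] * 10
        t = TallyTable.from_predictions(y_true, y_pred)
        assert t.table.loc["visual", "T"] == 5
        assert t.table.loc["visual", "C"] == 4
        assert t.table.loc["auditory", "C"] == 15
        assert t.table.loc["cognitive", "C"] == 0


class TestReplay:
    def test_oracle_decoder_scores_one(self, small_recording):
        truths = truth_per_chunk(small_recording)
        it = iter(truths)
        log, tally = replay_online(small_recording, lambda chunk: next(it))
        assert tally.overall_accuracy == 1.0
        assert len(log) == int(small_recording.duration_s)

    def test_event_contributes_duration_many_windows(self):
        """A 15-s auditory event yields exactly 15 tallied auditory chunks."""
        from neurodrive.synthetic import DesignEvent, EffectProfile, simulate_eeg

        events = [DesignEvent(5.0, "auditory", 15.0, 0)]
        rec = simulate_eeg(events, EffectProfile.default(1.0), duration_s=25.0,
                           fs=200.0, seed=0)
        _, tally = replay_online(rec, lambda chunk: "auditory")
        assert tally.table.loc["auditory", "T"] == 15
        assert tally.table.loc["auditory", "C"] == 15
        assert tally.table.loc["focused", "T"] == 10

    def test_chunk_shape_after_online_preprocessing(self, small_recording):
        shapes = []
        replay_online(small_recording,
                      lambda chunk: shapes.append(chunk.shape) or "focused")
        assert set(shapes) == {(59, 100)}

    def test_offline_online_feature_equivalence_same_band(self):
        """With identical filter bands, the offline chain and the chunk
        chain produce identical features for the same 1-s input."""
        from neurodrive.io import EventMarker, RawRecording
        from neurodrive.montage import CHANNELS_64
        from neurodrive.preprocess import (PreprocessConfig, preprocess_chunk,
                                           preprocess_recording)

        rng = np.random.default_rng(1)
        data = rng.standard_normal((64, 1000)) * 5
        rec = RawRecording(data, 1000.0, list(CHANNELS_64),
                           [EventMarker(0, "visual", 1.0)])
        cfg = PreprocessConfig(0.5, 45.0, name="shared")
        offline = preprocess_recording(rec, preset=cfg, reject=False)
        online = preprocess_chunk(data, 1000.0, list(CHANNELS_64), preset=cfg)
        assert len(offline) == 1
        np.testing.assert_allclose(offline[0].data, online, atol=1e-9)

    def test_sum_T_equals_processed_chunks(self, small_recording):
        log, tally = replay_online(small_recording, lambda chunk: "focused")
        assert int(tally.table["T"].sum()) == len(log)
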