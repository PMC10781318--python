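"""Participant-grouped splits, the RBF-SVM, and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

import thermoface as tf
from thermoface import state_classifier as sc


def _blob_table(rng, n_subjects=10, frames=4, sep=5.0, noise=0.3):
    """Well-separated Gaussian clusters per state; one subject = frames x 3 rows."""
    centers = {
        "baseline": np.array([33.0, 35.0, 34.5, 35.5, 34.5]),
        "stress": np.array([33.0, 35.0, 34.5, 35.5, 34.5]) + sep * np.array([1, 0, -1, 0.5, 0]) / 3,
        "relax": np.array([33.0, 35.0, 34.5, 35.5, 34.5]) + sep * np.array([-1, 0.5, 1, 0, -0.5]) / 3,
    }
    rows = []
    for s in range(n_subjects):
        for phase, mu in centers.items():
            for k in range(frames):
                x = mu + rng.normal(0, noise, 5)
                rows.append(
                    {"participant_id": f"p{s:02d}", "frame_id": f"p{s}_{phase}_{k}",
                     "phase": phase, **dict(zip(tf.ROI_NAMES, x))}
                )
    return pd.DataFrame(rows)


@pytest.fixture
def blobs(rng):
    return _blob_table(rng)


class TestSplitByParticipant:
    def test_counts_and_disjointness(self, blobs):
        train, test = sc.split_by_participant(blobs, n_train=8, n_test=2, seed=0)
        assert len(train) == 8 * 12 and len(test) == 2 * 12
        assert not set(train["participant_id"]) & set(test["participant_id"])
        assert len(train) + len(test) == len(blobs)

    def test_default_protocol_counts(self):
        rng = np.random.default_rng(0)
        table = _blob_table(rng, n_subjects=25)
        train, test = sc.split_by_participant(table, seed=3)
        assert len(train) == 240 and len(test) == 60

    def test_seed_determinism(self, blobs):
        a = sc.split_by_participant(blobs, n_train=8, n_test=2, seed=5)
        b = sc.split_by_participant(blobs, n_train=8, n_test=2, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_too_few_participants_rejected(self, blobs):
        with pytest.raises(ValueError):
            sc.split_by_participant(blobs, n_train=20, n_test=5)


class TestTrain:
    def test_separable_clusters_reach_full_training_accuracy(self, blobs):
        model = sc.train(blobs, sc.ClassifierConfig(seed=0))
        pred = sc.predict(model, blobs)
        assert (pred == blobs["phase"].to_numpy()).mean() == 1.0

    def test_single_class_rejected(self, blobs):
        only = blobs[blobs["phase"] == "stress"]
        with pytest.raises(ValueError):
            sc.train(only, sc.ClassifierConfig())

    def test_run_to_run_determinism(self, blobs):
        p1 = sc.predict(sc.train(blobs, sc.ClassifierConfig(seed=2)), blobs)
        p2 = sc.predict(sc.train(blobs, sc.ClassifierConfig(seed=2)), blobs)
        assert (p1 == p2).all()

    def test_grid_search_tie_break_matches_exhaustive_oracle(self, blobs):
        grid = {"C": [1.0, 100.0], "gamma": [0.1, 10.0]}
        cfg = sc.ClassifierConfig(grid=grid, seed=0)
        model = sc.train(blobs, cfg)
        # oracle: evaluate every combination with the same folds and pick the
        # argmax, smallest C then smallest gamma on ties
        scores = {}
        folds = sc._participant_folds(blobs, cfg.k_folds, cfg.seed)
        X = blobs[list(tf.ROI_NAMES)].to_numpy()
        y = blobs["phase"].to_numpy()
        from sklearn.svm import SVC

        for C in grid["C"]:
            for gamma in grid["gamma"]:
                correct = 0
                for m in folds:
                    est = SVC(C=C, gamma=gamma, random_state=0)
                    est.fit(X[~m], y[~m])
                    correct += (est.predict(X[m]) == y[m]).sum()
                scores[(C, gamma)] = correct / len(y)
        best = max(scores.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))[0]
        assert (model.chosen_params["C"], model.chosen_params["gamma"]) == best

    def test_duplicated_rows_barely_change_predictions(self, blobs, rng):
        m1 = sc.train(blobs, sc.ClassifierConfig(seed=0))
        doubled = pd.concat([blobs, blobs], ignore_index=True)
        m2 = sc.train(doubled, sc.ClassifierConfig(seed=0))
        grid = blobs.copy()
        grid[list(tf.ROI_NAMES)] += rng.normal(0, 0.2, size=(len(grid), 5))
        agree = (sc.predict(m1, grid) == sc.predict(m2, grid)).mean()
        assert agree >= 0.99


class TestPredict:
    def test_training_row_re_predicted(self, blobs):
        model = sc.train(blobs, sc.ClassifierConfig())
        row = blobs.iloc[0]
        assert sc.predict(model, row[list(tf.ROI_NAMES)]) == row["phase"]

    def test_feature_order_irrelevant_for_named_inputs(self, blobs):
        model = sc.train(blobs, sc.ClassifierConfig())
        feats = {r: blobs.iloc[5][r] for r in tf.ROI_NAMES}
        shuffled = dict(reversed(list(feats.items())))
        assert sc.predict(model, feats) == sc.predict(model, shuffled)
        df = blobs.iloc[[5]][["chin", "nose", "forehead", "left_cheek", "right_cheek",
                             "participant_id", "frame_id", "phase"]]
        assert sc.predict(model, df)[0] == sc.predict(model, feats)

    def test_batch_equals_per_row_loop(self, blobs):
        model = sc.train(blobs, sc.ClassifierConfig())
        batch = sc.predict(model, blobs.head(20))
        loop = [sc.predict(model, blobs.iloc[i][list(tf.ROI_NAMES)]) for i in range(20)]
        assert list(batch) == loop

    def test_missing_feature_rejected(self, blobs):
        model = sc.train(blobs, sc.ClassifierConfig())
        with pytest.raises(ValueError, match="missing features"):
            sc.predict(model, {"nose": 33.0})


class TestKfoldCV:
    def test_pooled_report_covers_every_row(self, blobs):
        report = sc.kfold_cv(blobs, sc.ClassifierConfig(seed=0))
        assert report.confusion.sum() == len(blobs)
        assert report.overall_accuracy >= 90.0  # separable clusters

    def test_leave_one_subject_out_matches_brute_force(self, rng):
        table = _blob_table(rng, n_subjects=6, noise=0.6)
        n = table["participant_id"].nunique()
        report = sc.kfold_cv(table, sc.ClassifierConfig(k_folds=n, seed=1))
        # brute force: explicitly hold out each subject
        y_pred = pd.Series(index=table.index, dtype=object)
        for pid in table["participant_id"].unique():
            mask = (table["participant_id"] == pid).to_numpy()
            model = sc.train(table[~mask], sc.ClassifierConfig(seed=1))
            y_pred[mask] = sc.predict(model, table[mask])
        cm = sc.confusion_matrix(table["phase"].to_numpy(), y_pred.to_numpy())
        assert np.array_equal(report.confusion, cm)

    def test_impossible_folding_raises(self):
        rows = []
        for s, phase in enumerate(["baseline", "relax", "stress"]):
            for k in range(4):
                rows.append({"participant_id": f"p{s}", "frame_id": f"{s}{k}",
                             "phase": phase, **{r: 33.0 + s for r in tf.ROI_NAMES}})
        table = pd.DataFrame(rows)  # each class lives in exactly one subject
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                sc.kfold_cv(table, sc.ClassifierConfig(k_folds=3, seed=0))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["baseline"] * 3 + ["relax"] * 4 + ["stress"] * 5
        cm = sc.confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([3, 4, 5]))

    def test_constant_prediction_single_column(self):
        y = ["baseline", "relax", "stress", "stress"]
        cm = sc.confusion_matrix(y, ["relax"] * 4)
        assert cm[:, [0, 2]].sum() == 0 and cm[:, 1].sum() == 4

    def test_matches_tally_oracle(self, rng):
        labels = np.array(sc.CLASS_ORDER)
        y_true = labels[rng.integers(0, 3, 50)]
        y_pred = labels[rng.integers(0, 3, 50)]
        cm = sc.confusion_matrix(y_true, y_pred)
        for i, ci in enumerate(sc.CLASS_ORDER):
            for j, cj in enumerate(sc.CLASS_ORDER):
                assert cm[i, j] == int(np.sum((y_true == ci) & (y_pred == cj)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            sc.confusion_matrix(["baseline"], ["acclimatization"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.confusion_matrix(["baseline"], ["baseline", "relax"])


class TestClassificationReport:
    def test_published_shape_matrix(self):
        """The 66-frame matrix with three errors reproduces the printed metrics."""
        cm = np.array([[21, 1, 1], [0, 24, 0], [0, 1, 18]])
        rep = sc.classification_report(cm)
        assert rep.precision_pct == {"baseline": 100, "relax": 92, "stress": 95}
        assert rep.recall_2dp["baseline"] == 91.30
        assert rep.recall_2dp["relax"] == 100.0
        assert rep.recall_2dp["stress"] == pytest.approx(94.74, abs=0.011)
        assert rep.f1_pct == {"baseline": 95, "relax": 96, "stress": 95}
        assert rep.overall_accuracy == pytest.approx(95.45, abs=0.005)
        assert rep.error_rate == pytest.approx(4.55, abs=0.005)

    def test_identity_matrix_all_perfect(self):
        rep = sc.classification_report(np.diag([5, 5, 5]))
        assert rep.precision_pct == rep.recall_pct == rep.f1_pct
        assert all(v == 100 for v in rep.f1_pct.values())
        assert rep.overall_accuracy == 100.0

    def test_f1_of_92_and_100_prints_96(self):
        assert sc.f1_from_pair(92, 100) == pytest.approx(95.83, abs=0.005)
        assert sc._int_pct(sc.f1_from_pair(92, 100)) == 96

    def test_accuracy_plus_error_is_exactly_100(self, rng):
        cm = rng.integers(0, 20, size=(3, 3))
        cm[0, 0] += 1
        rep = sc.classification_report(cm)
        assert rep.overall_accuracy + rep.error_rate == 100.0

    def test_zero_prediction_column_gives_nan_with_warning(self):
        cm = np.array([[5, 0, 2], [0, 0, 3], [0, 0, 7]])
        with pytest.warns(UserWarning, match="precision undefined"):
            rep = sc.classification_report(cm)
        assert np.isnan(rep.precision["relax"])
        assert rep.precision_pct["baseline"] == 100
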