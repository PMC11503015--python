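"""Splitting, metric suite (vs independent oracles) and training behaviour."""

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score

from semgait.errors import DataError
from semgait.features import WindowSpec, segment
from semgait.model import ModelConfig, MultiBranchNet
from semgait.preprocess import extract_gait_phases, smooth_pressure, standardize
from semgait.simulate import SimConfig, generate_session
from semgait.traineval import (
    SplitSpec,
    TrainConfig,
    classification_metrics,
    confusion_matrix,
    evaluate,
    regression_metrics,
    split,
    train,
)

TINY_MODEL = ModelConfig(conv1d_channels=(6, 8), conv2d_channels=4,
                         gru_hidden=10, fc_hidden=16)


def brute_force_metrics(cm):
    """Independent plain-Python implementation from the confusion counts."""
    k = len(cm)
    tp = [cm[i][i] for i in range(k)]
    col = [sum(cm[r][c] for r in range(k)) for c in range(k)]
    row = [sum(cm[r]) for r in range(k)]
    total = sum(row)
    prec = [tp[c] / col[c] if col[c] > 0 else 0.0 for c in range(k)]
    sens = [tp[r] / row[r] if row[r] > 0 else 0.0 for r in range(k)]
    present = [r for r in range(k) if row[r] > 0]
    return {
        "accuracy": sum(tp) / total * 100.0,
        "pmap": sum(prec[c] for c in present) / len(present) * 100.0,
        "pmas": sum(sens[c] for c in present) / len(present) * 100.0,
        "pmip": sum(tp) / sum(col) * 100.0,
        "pmis": sum(tp) / sum(row) * 100.0,
        "precision": [p * 100.0 for p in prec],
        "sensitivity": [s * 100.0 for s in sens],
    }


@pytest.fixture(scope="module")
def featureset():
    cfg = SimConfig(n_cycles=24, seed=33)
    rec = generate_session(cfg)
    labels = extract_gait_phases(smooth_pressure(rec.pressure, 0.02, cfg.sampling_rate),
                                 cfg.sampling_rate)
    rec.semg = standardize(rec.semg)
    rec.labels = labels
    return segment(rec, WindowSpec(320, 160))


class TestSplit:
    def test_sizes_and_disjointness(self, featureset):
        tr, te = split(featureset, SplitSpec(group_by_cycle=False, seed=1))
        assert len(tr) == round(0.8 * len(featureset))
        assert len(tr) + len(te) == len(featureset)
        assert set(tr.window_start) & set(te.window_start) == set()

    def test_group_by_cycle_keeps_cycles_whole(self, featureset):
        tr, te = split(featureset, SplitSpec(group_by_cycle=True, seed=2))
        assert set(tr.cycle_index) & set(te.cycle_index) == set()
        assert len(tr) + len(te) == len(featureset)

    def test_stratified_preserves_class_proportions(self, featureset):
        spec = SplitSpec(group_by_cycle=False, stratify_by_gait=True, seed=3)
        tr, te = split(featureset, spec)
        for cls in np.unique(featureset.gait):
            n_cls = int(np.sum(featureset.gait == cls))
            got = int(np.sum(tr.gait == cls))
            assert abs(got - 0.8 * n_cls) <= 1

    def test_deterministic_given_seed(self, featureset):
        a, _ = split(featureset, SplitSpec(seed=5))
        b, _ = split(featureset, SplitSpec(seed=5))
        assert np.array_equal(a.window_start, b.window_start)


class TestClassificationMetrics:
    def test_diagonal_confusion_is_perfect(self):
        m = classification_metrics(np.diag([10, 20, 30, 40]))
        assert m["accuracy"] == 100.0
        assert m["pmap"] == m["pmip"] == m["pmas"] == m["pmis"] == 100.0
        assert np.all(m["per_class_precision"] == 100.0)

    def test_two_phase_toy_confusion(self):
        """[[8,2],[3,7]]: accuracy 75%, macro precision (8/11 + 7/9)/2."""
        m = classification_metrics(np.array([[8, 2], [3, 7]]))
        assert m["accuracy"] == pytest.approx(75.0)
        assert m["pmap"] == pytest.approx((8 / 11 + 7 / 9) / 2 * 100)
        assert m["pmas"] == pytest.approx((8 / 10 + 7 / 10) / 2 * 100)

    def test_micro_identities_on_random_confusions(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            cm = rng.integers(0, 50, size=(4, 4))
            if cm.sum() == 0:
                continue
            m = classification_metrics(cm)
            assert m["pmip"] == m["pmis"] == m["accuracy"]

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            cm = rng.integers(0, 30, size=(4, 4))
            if cm.sum() == 0 or np.any(cm.sum(axis=1) == 0):
                cm = cm + 1
            with np.errstate(all="ignore"):
                m = classification_metrics(cm)
            o = brute_force_metrics(cm.tolist())
            assert m["accuracy"] == o["accuracy"]
            assert m["pmap"] == o["pmap"]
            assert m["pmas"] == o["pmas"]
            assert m["pmip"] == o["pmip"]
            assert m["pmis"] == o["pmis"]
            assert np.array_equal(m["per_class_precision"], o["precision"])
            assert np.array_equal(m["per_class_sensitivity"], o["sensitivity"])

    def test_matches_sklearn_on_label_streams(self, rng):
        true = rng.integers(0, 4, size=500)
        pred = rng.integers(0, 4, size=500)
        cm = confusion_matrix(true, pred)
        m = classification_metrics(cm)
        assert m["pmap"] == pytest.approx(
            precision_score(true, pred, average="macro", zero_division=0) * 100)
        assert m["pmas"] == pytest.approx(
            recall_score(true, pred, average="macro", zero_division=0) * 100)

    def test_zero_predicted_class_warns_and_reports_zero(self):
        cm = np.array([[0, 5, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]])
        with pytest.warns(UserWarning):
            m = classification_metrics(cm)
        assert m["per_class_precision"][0] == 0.0


class TestRegressionMetrics:
    def test_perfect_prediction(self, rng):
        true = rng.uniform(-20, 45, size=(100, 3))
        m = regression_metrics(true, true)
        assert np.allclose(m["rmse"], 0.0)
        assert np.allclose(m["xcorr"], 1.0)

    def test_constant_offset(self, rng):
        true = rng.uniform(-20, 45, size=(200, 3))
        m = regression_metrics(true + 1.0, true)
        assert np.allclose(m["rmse"], 1.0)
        assert np.allclose(m["xcorr"], 1.0)  # Pearson is shift-invariant

    def test_negated_zero_mean_series_anticorrelates(self):
        t = np.linspace(0, 4 * np.pi, 300)
        true = np.stack([np.sin(t), np.cos(t), np.sin(2 * t)], axis=1)
        m = regression_metrics(-true, true)
        assert np.allclose(m["xcorr"], -1.0)

    def test_relative_error_uses_observed_range(self, rng):
        true = np.zeros((100, 3))
        true[:, 0] = np.linspace(0, 10, 100)   # range 10
        true[:, 1] = np.linspace(-5, 5, 100)   # range 10
        true[:, 2] = np.linspace(0, 50, 100)   # range 50
        m = regression_metrics(true + 1.0, true)
        assert m["relative_error"][0] == pytest.approx(10.0)
        assert m["relative_error"][2] == pytest.approx(2.0)


class TestTraining:
    def test_loss_curve_finite_and_decreasing(self, featureset):
        tr, _ = split(featureset, SplitSpec(seed=0))
        net = MultiBranchNet(TINY_MODEL, seed=0)
        hist = train(net, tr, TrainConfig(epochs=3, seed=0))
        assert np.all(np.isfinite(hist["train_loss"]))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_fixed_seed_reproduces_curve(self, featureset):
        tr, _ = split(featureset, SplitSpec(seed=0))
        hists = []
        for _ in range(2):
            net = MultiBranchNet(TINY_MODEL, seed=1)
            hists.append(train(net, tr, TrainConfig(epochs=2, seed=1)))
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_accuracy"] == hists[1]["val_accuracy"]

    def test_evaluate_report_is_complete(self, featureset):
        tr, te = split(featureset, SplitSpec(seed=0))
        net = MultiBranchNet(TINY_MODEL, seed=0)
        train(net, tr, TrainConfig(epochs=2, seed=0))
        report = evaluate(net, te)
        assert report.confusion.sum() == len(te)
        assert np.isfinite(report.accuracy)
        assert report.per_joint_rmse.shape == (3,)
        assert np.all(np.isfinite(report.per_joint_rmse))
        assert np.all(np.abs(report.per_joint_xcorr) <= 1.0 + 1e-12)
        # rerun on the same weights gives the identical report
        again = evaluate(net, te)
        assert np.array_equal(report.confusion, again.confusion)
        assert report.accuracy == again.accuracy

    def test_more_noise_does_not_help_accuracy(self):
        """5x measurement noise must not increase held-out gait accuracy
        (3 seeds, small training scale; ties tolerated)."""
        def run(noise_sd, seed):
            cfg = SimConfig(n_cycles=16, measurement_noise_sd=noise_sd, seed=seed)
            rec = generate_session(cfg)
            rec.semg = standardize(rec.semg)
            feats = segment(rec, WindowSpec(320, 160))
            tr, te = split(feats, SplitSpec(seed=seed))
            net = MultiBranchNet(TINY_MODEL, seed=seed)
            train(net, tr, TrainConfig(epochs=3, seed=seed))
            return evaluate(net, te).accuracy

        base = np.mean([run(0.05, s) for s in (0, 1, 2)])
        noisy = np.mean([run(0.25, s) for s in (0, 1, 2)])
        assert noisy <= base + 2.0

    def test_empty_test_set_rejected(self, featureset):
        net = MultiBranchNet(TINY_MODEL, seed=0)
        with pytest.raises(DataError):
            evaluate(net, featureset.subset(np.array([], dtype=int)))
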