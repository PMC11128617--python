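"""Training loop, k-fold protocol, metric identities and Grad-CAM contracts."""

import numpy as np
import pytest

from seednet.network_builder import VariantConfig, build_model
from seednet.synthetic_data import SyntheticSpec, generate_dataset
from seednet.training_eval import (EvalReport, TrainConfig, _cross_entropy,
                                   cross_validate, evaluate, f1_score,
                                   grad_cam, kfold_splits,
                                   report_from_confusion, train)

# per-class (precision %, recall %, F1) for the published six varieties,
# before and after the architecture improvements
PER_CLASS_METRICS = [
    ("JD407", 86.8, 84.6, 0.857, 92.5, 94.9, 0.937),
    ("JD50", 82.2, 80.5, 0.813, 87.0, 92.8, 0.898),
    ("JD83", 91.7, 90.8, 0.912, 95.2, 91.8, 0.935),
    ("JD953", 79.7, 83.9, 0.817, 92.9, 88.5, 0.906),
    ("JD209", 80.0, 88.4, 0.84, 88.3, 91.0, 0.896),
    ("JD626", 85.4, 76.8, 0.809, 92.1, 88.4, 0.902),
]


@pytest.fixture(scope="module")
def mini_dataset():
    return generate_dataset(SyntheticSpec(n_per_class=20, image_size=32,
                                          rng_seed=7))


@pytest.fixture()
def mini_model(tiny_plan):
    return build_model(VariantConfig(True, True, True), plan=tiny_plan,
                       rng=np.random.default_rng(0))


class TestTrainConfig:
    def test_defaults_follow_protocol(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.learning_rate, cfg.momentum,
                cfg.weight_decay, cfg.optimizer, cfg.folds) == \
            (150, 32, 0.001, 0.9, 0.0005, "sgd", 5)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(momentum=1.0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="adam")
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestKFold:
    def test_balanced_six_class_folds(self):
        labels = np.repeat(np.arange(6), 10)
        folds = kfold_splits(labels, k=5, rng_seed=1)
        assert len(folds) == 5
        for tr, va in folds:
            assert len(va) == 12
            assert np.bincount(labels[va], minlength=6).tolist() == [2] * 6
        union = np.sort(np.concatenate([va for _, va in folds]))
        np.testing.assert_array_equal(union, np.arange(60))

    def test_reproducible_under_seed(self):
        labels = np.repeat(np.arange(3), 20)
        a = kfold_splits(labels, k=5, rng_seed=9)
        b = kfold_splits(labels, k=5, rng_seed=9)
        for (t1, v1), (t2, v2) in zip(a, b):
            np.testing.assert_array_equal(v1, v2)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            kfold_splits([0, 0, 0, 1, 1, 1, 1, 1], k=5)


class TestTrain:
    def test_zero_learning_rate_freezes_parameters(self, mini_model,
                                                   mini_dataset):
        X, y = mini_dataset
        before = {k: v.copy() for k, v in mini_model.state_dict().items()
                  if not k.endswith(("running_mean", "running_var"))}
        train(mini_model, X[:32], y[:32],
              TrainConfig(epochs=1, batch_size=16, learning_rate=0.0,
                          weight_decay=0.0))
        after = mini_model.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k])

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_decreases_between_first_epochs(self, tiny_plan,
                                                 mini_dataset, seed):
        X, y = mini_dataset
        model = build_model(VariantConfig(True, True, True), plan=tiny_plan,
                            rng=np.random.default_rng(seed))
        hist = train(model, X, y, TrainConfig(epochs=2, batch_size=16,
                                              learning_rate=0.01,
                                              rng_seed=seed))
        assert len(hist) == 2
        assert hist[1]["loss"] < hist[0]["loss"]

    def test_empty_dataset_rejected(self, mini_model):
        with pytest.raises(ValueError):
            train(mini_model, np.zeros((0, 32, 32, 3), np.uint8),
                  np.zeros(0, np.int64))

    def test_history_length_equals_epochs(self, mini_model, mini_dataset):
        X, y = mini_dataset
        hist = train(mini_model, X[:32], y[:32],
                     TrainConfig(epochs=3, batch_size=16, learning_rate=0.01))
        assert [h["epoch"] for h in hist] == [1, 2, 3]


class TestCrossEntropy:
    def test_matches_closed_form(self):
        logits = np.log(np.array([[0.7, 0.2, 0.1]]))
        loss, grad = _cross_entropy(logits, np.array([0]))
        assert loss == pytest.approx(-np.log(0.7))
        np.testing.assert_allclose(grad.sum(), 0.0, atol=1e-12)

    def test_uniform_logits_give_log_k(self):
        loss, _ = _cross_entropy(np.zeros((4, 6)), np.array([0, 1, 2, 3]))
        assert loss == pytest.approx(np.log(6))


class TestMetrics:
    @pytest.mark.parametrize(
        "name,p0,r0,f0,p1,r1,f1", PER_CLASS_METRICS,
        ids=[row[0] for row in PER_CLASS_METRICS])
    def test_published_f1_consistency(self, name, p0, r0, f0, p1, r1, f1):
        """The harmonic-mean identity reproduces every printed F1 from its
        printed precision/recall pair, at the printed precision."""
        for p, r, f in ((p0, r0, f0), (p1, r1, f1)):
            dp = len(str(f).split(".")[1])
            assert abs(f1_score(p / 100, r / 100) - f) <= 0.5 * 10 ** -dp

    def test_perfect_prediction_report(self):
        conf = np.diag([5, 7, 3])
        rep = report_from_confusion(conf)
        assert rep.accuracy == 1.0
        assert all(f == 1.0 for _, _, f in rep.per_class)
        assert rep.n == 15

    def test_confusion_identities_hold_on_random_matrices(self, rng):
        for _ in range(20):
            conf = rng.integers(0, 30, (6, 6))
            if conf.sum() == 0:
                continue
            rep = report_from_confusion(conf)
            assert rep.confusion.sum() == rep.n
            assert rep.accuracy == pytest.approx(np.trace(conf) / conf.sum())
            # micro-averaged precision equals accuracy for single-label tasks
            tp = np.diag(conf).sum()
            predicted = conf.sum()
            assert tp / predicted == pytest.approx(rep.accuracy)
            # per-class TP + FN is the row sum
            for c in range(6):
                tp_c = conf[c, c]
                fn_c = conf[c].sum() - tp_c
                assert tp_c + fn_c == conf[c].sum()

    def test_zero_predicted_class_warns(self):
        conf = np.array([[3, 0], [2, 0]])
        with pytest.warns(UserWarning, match="no predicted positives"):
            rep = report_from_confusion(conf)
        assert rep.per_class[1][0] == 0.0

    def test_evaluate_returns_consistent_report(self, mini_model,
                                                mini_dataset):
        X, y = mini_dataset
        rep = evaluate(mini_model, X[:30], y[:30])
        assert isinstance(rep, EvalReport)
        assert rep.n == 30
        assert rep.confusion.shape == (6, 6)
        assert 0.0 <= rep.accuracy <= 1.0


class TestCrossValidate:
    def test_permuted_labels_score_at_chance(self, tiny_plan, mini_dataset):
        """5-fold mean accuracy on label-permuted data sits at ~1/6."""
        X, y = mini_dataset
        yp = np.random.default_rng(13).permutation(y)
        res = cross_validate(
            lambda: build_model(VariantConfig(True, True, True),
                                plan=tiny_plan,
                                rng=np.random.default_rng(1)),
            X, yp, TrainConfig(epochs=3, batch_size=16, learning_rate=0.01,
                               folds=5, rng_seed=1))
        assert abs(res["mean_accuracy"] - 1 / 6) <= 0.06
        assert len(res["fold_reports"]) == 5


class TestGradCam:
    def test_heatmap_contracts(self, mini_model, mini_dataset):
        X, _ = mini_dataset
        heat = grad_cam(mini_model, X[0], target_class=0)
        assert heat.shape == (32, 32)
        assert heat.min() >= 0.0 and heat.max() <= 1.0
        assert heat.max() == pytest.approx(1.0) or not heat.any()

    def test_invalid_arguments(self, mini_model, mini_dataset):
        X, _ = mini_dataset
        with pytest.raises(ValueError):
            grad_cam(mini_model, X[0], target_class=17)
        with pytest.raises(ValueError):
            grad_cam(mini_model, X[0], target_class=0, stage_index=5)

    def test_stage_selection(self, mini_model, mini_dataset):
        X, _ = mini_dataset
        a = grad_cam(mini_model, X[0], 0, stage_index=0)
        b = grad_cam(mini_model, X[0], 0, stage_index=-1)
        assert a.shape == b.shape == (32, 32)
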