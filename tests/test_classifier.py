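"""Classifier building blocks: focal loss, splits, metrics, training loop."""

import math
import warnings

import numpy as np
import pytest

from nodulecam import nn
from nodulecam.classifier import (
    BackboneConfig,
    ConfusionTable,
    FocalLossParams,
    NoduleCNNClassifier,
    _focal_loss_and_grad_logits,
    build_model,
    compute_metrics,
    confusion_from_predictions,
    focal_loss,
    preprocess,
    repeat_experiment,
    roc_auc,
    stratified_split,
)


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        # alpha 0.5 gives alpha_t = 1/2 for both classes; doubling recovers CE
        p = 0.5
        assert 2 * focal_loss(p, 1, FocalLossParams(alpha=0.5, gamma=0.0)) == pytest.approx(
            -math.log(0.5)
        )

    def test_direct_evaluation(self):
        # 0.25 * (0.1)^2 * (-ln 0.9)
        expected = 0.25 * 0.01 * -math.log(0.9)
        assert focal_loss(0.9, 1, FocalLossParams(0.25, 2.0)) == pytest.approx(expected)
        assert expected == pytest.approx(2.6341e-4, rel=1e-4)

    def test_class_symmetry(self):
        # p=0.9, y=0 is the mirror of p=0.1, y=1 with alpha roles swapped
        a = focal_loss(0.9, 0, FocalLossParams(0.25, 2.0))
        b = focal_loss(0.1, 1, FocalLossParams(0.75, 2.0))
        assert a == pytest.approx(b)

    def test_ce_limit_on_grid(self):
        """gamma=0, alpha_t=1: focal loss equals -log(p_t) to 1e-12."""
        p = np.linspace(1e-6, 1 - 1e-6, 1000)
        fl1 = 2 * focal_loss(p, np.ones_like(p), FocalLossParams(0.5, 0.0), reduce=False)
        fl0 = 2 * focal_loss(p, np.zeros_like(p), FocalLossParams(0.5, 0.0), reduce=False)
        assert np.abs(fl1 - (-np.log(p))).max() < 1e-12
        assert np.abs(fl0 - (-np.log(1 - p))).max() < 1e-12

    def test_nonnegative_and_decreasing_in_pt(self):
        p = np.linspace(0.01, 0.99, 99)
        loss = focal_loss(p, np.ones_like(p), FocalLossParams(0.25, 2.0), reduce=False)
        assert (loss >= 0).all()
        assert (np.diff(loss) < 0).all()

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(1.2, 1)

    def test_boundary_probabilities_clamped_finite(self):
        assert np.isfinite(focal_loss(0.0, 1))
        assert np.isfinite(focal_loss(1.0, 0))

    @pytest.mark.parametrize("gamma", [0.0, 0.5, 2.0])
    def test_logit_gradient_matches_finite_differences(self, gamma, rng):
        params = FocalLossParams(0.25, gamma)
        logits = rng.normal(size=(6, 2))
        y = rng.integers(0, 2, size=6)
        _, grad = _focal_loss_and_grad_logits(logits, y, params)
        eps = 1e-6
        for i in range(6):
            for j in range(2):
                lp, lm = logits.copy(), logits.copy()
                lp[i, j] += eps
                lm[i, j] -= eps
                num = (
                    _focal_loss_and_grad_logits(lp, y, params)[0]
                    - _focal_loss_and_grad_logits(lm, y, params)[0]
                ) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-7)


class TestStratifiedSplit:
    def test_clinical_table_arithmetic(self):
        labels = ["benign"] * 415 + ["malignant"] * 93
        split = stratified_split(labels, 0.7, seed=0)
        assert split.train_counts == {"benign": 291, "malignant": 66}
        assert split.test_counts == {"benign": 124, "malignant": 27}
        assert len(split.train_idx) == 357 and len(split.test_idx) == 151

    def test_small_balanced_split(self):
        labels = ["benign"] * 10 + ["malignant"] * 10
        split = stratified_split(labels, 0.7, seed=1)
        assert split.train_counts == {"benign": 7, "malignant": 7}
        assert split.test_counts == {"benign": 3, "malignant": 3}

    def test_disjoint_and_exhaustive(self, rng):
        for _ in range(20):
            n_b, n_m = rng.integers(2, 40, size=2)
            labels = ["benign"] * int(n_b) + ["malignant"] * int(n_m)
            frac = float(rng.uniform(0.3, 0.9))
            split = stratified_split(labels, frac, seed=int(rng.integers(1e6)))
            joined = np.concatenate([split.train_idx, split.test_idx])
            assert len(set(joined.tolist())) == len(labels)
            assert split.train_counts["benign"] == math.ceil(frac * n_b)

    def test_full_train_fraction_warns(self):
        with pytest.warns(UserWarning):
            split = stratified_split(["benign", "malignant"], 1.0, seed=0)
        assert len(split.test_idx) == 0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["benign", "benign"], 0.7, seed=0)
        with pytest.raises(ValueError):
            stratified_split([], 0.7, seed=0)


class TestMetrics:
    def test_hand_arithmetic(self):
        m = compute_metrics(ConfusionTable(TP=9, TN=88, FP=1, FN=2))
        assert m["accuracy"] == pytest.approx(0.97)
        assert m["recall"] == pytest.approx(9 / 11)
        assert m["precision"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionTable(TP=5, TN=7, FP=0, FN=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "recall", "precision", "f1"))

    def test_undefined_precision_reported_as_nan(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(ConfusionTable(TP=0, TN=5, FP=0, FN=3))
        assert m["recall"] == 0.0
        assert math.isnan(m["precision"])

    def test_agrees_with_brute_force_recount(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            table = confusion_from_predictions(y, pred)
            # independent recount
            tp = sum(1 for a, b in zip(y, pred) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(y, pred) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y, pred) if a == 1 and b == 0)
            tn = n - tp - fp - fn
            assert (table.TP, table.TN, table.FP, table.FN) == (tp, tn, fp, fn)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(table)
            assert m["accuracy"] == pytest.approx((tp + tn) / n)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_agrees_with_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 60))
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                continue
            s = rng.random(n)
            auc, curve = roc_auc(s, y)
            pos = s[y == 1]
            neg = s[y == 0]
            pairs = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(pairs / (len(pos) * len(neg)))
            assert curve.shape[1] == 3


class TestPreprocess:
    def test_eval_mode_idempotent_on_sized_input(self, rng):
        img = rng.random((64, 64))
        a = preprocess(img, input_size=64)
        b = preprocess(a[0] * 0.25 + 0.5, input_size=64)  # undo normalization
        assert np.allclose(a, b, atol=1e-6)

    def test_same_augment_seed_identical(self, rng):
        img = rng.random((64, 64))
        a = preprocess(img, train_mode=True, augment_seed=9, input_size=64)
        b = preprocess(img, train_mode=True, augment_seed=9, input_size=64)
        assert np.array_equal(a, b)

    def test_resize_to_target(self, rng):
        out = preprocess(rng.random((100, 80)), input_size=48)
        assert out.shape == (1, 48, 48)


class TestBuildModel:
    def test_resnet18_feature_maps_are_7x7_at_224(self):
        model = build_model(BackboneConfig(variant="resnet18"))
        logits = model.forward(np.zeros((1, 1, 224, 224), dtype=np.float32))
        assert logits.shape == (1, 2)
        assert model.feature_maps_.shape[2:] == (7, 7)
        assert model.feature_maps_.shape[1] == 512

    def test_tiny_smoke_on_64(self, rng):
        model = build_model(BackboneConfig(variant="tiny"))
        logits = model.forward(rng.normal(size=(2, 1, 64, 64)).astype(np.float32))
        assert logits.shape == (2, 2)
        assert np.isfinite(logits).all()

    def test_softmax_normalized(self, rng):
        model = build_model(BackboneConfig(variant="tiny"))
        logits = model.forward(rng.normal(size=(3, 1, 64, 64)).astype(np.float32))
        z = np.exp(logits - logits.max(axis=1, keepdims=True))
        assert np.allclose((z / z.sum(axis=1, keepdims=True)).sum(axis=1), 1.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model(BackboneConfig(variant="resnet50"))


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Full-network gradient check on a miniature float64 model."""
        model = nn.ResidualCNN(
            1, 2, stem_channels=4, stem_kernel=3, stem_stride=2, stem_pool=2,
            stage_channels=(4,), blocks_per_stage=(1,), stage_strides=(1,),
            rng=np.random.default_rng(1), dtype=np.float64,
        )
        x = rng.normal(size=(2, 1, 16, 16))
        y = np.array([0, 1])
        params = FocalLossParams(0.25, 2.0)

        def loss():
            logits = model.forward(x, train=True)
            return _focal_loss_and_grad_logits(logits, y, params)[0]

        logits = model.forward(x, train=True)
        _, dlog = _focal_loss_and_grad_logits(logits, y, params)
        model.zero_grad()
        model.backward(dlog)
        ps = model.params()
        for p in (ps[0], ps[3], ps[-2], ps[-1]):
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for idx in (0, len(flat) // 2, len(flat) - 1):
                old = flat[idx]
                flat[idx] = old + 1e-6
                lp = loss()
                flat[idx] = old - 1e-6
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / 2e-6
                assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_loss_decreases_on_small_problem(self, small_dataset):
        images, _ = small_dataset
        labels = [im.label for im in images]
        est = NoduleCNNClassifier(
            variant="tiny", learning_rate=3e-3, epochs=12, batch_size=8,
            input_size=64, augment=False, random_state=0,
        )
        est.fit(images, labels)
        assert est.loss_trace_[-1] < est.loss_trace_[0]
        assert np.isfinite(est.loss_trace_).all()

    def test_zero_epochs_keeps_model_at_init(self, small_dataset):
        images, _ = small_dataset
        labels = [im.label for im in images]
        est = NoduleCNNClassifier(variant="tiny", epochs=0, input_size=64, random_state=5)
        est.fit(images, labels)
        ref = est._build()
        for p, q in zip(est.model_.params(), ref.params()):
            assert np.array_equal(p.value, q.value)

    def test_single_class_rejected(self, small_dataset):
        images, _ = small_dataset
        benign = [im for im in images if im.label == "benign"]
        est = NoduleCNNClassifier(variant="tiny", epochs=1, input_size=64)
        with pytest.raises(ValueError):
            est.fit(benign, ["benign"] * len(benign))

    def test_checkpoint_round_trip(self, small_dataset, tmp_path):
        images, _ = small_dataset
        labels = [im.label for im in images]
        est = NoduleCNNClassifier(variant="tiny", epochs=2, input_size=64,
                                  augment=False, random_state=0)
        est.fit(images, labels)
        est.save(tmp_path / "ckpt.npz")
        loaded = NoduleCNNClassifier.load(tmp_path / "ckpt.npz")
        assert loaded.input_size == 64
        a = est.predict_proba(images[:4])
        b = loaded.predict_proba(images[:4])
        assert np.allclose(a, b)

    def test_sklearn_param_interface(self):
        est = NoduleCNNClassifier(variant="tiny", gamma=1.5)
        assert est.get_params()["gamma"] == 1.5
        est.set_params(gamma=3.0)
        assert est.gamma == 3.0


class TestRepeatExperiment:
    def test_single_repeat_equals_single_run(self, small_dataset):
        images, _ = small_dataset
        labels = [im.label for im in images]
        est = NoduleCNNClassifier(variant="tiny", epochs=3, input_size=64,
                                  augment=False, batch_size=8)
        report = repeat_experiment(images, labels, n_repeats=1, master_seed=0,
                                   estimator=est)
        assert len(report.per_repeat) == 1
        means = report.means
        assert means["auc"] == pytest.approx(report.per_repeat[0]["auc"])

    def test_means_within_per_repeat_range(self, small_dataset):
        images, _ = small_dataset
        labels = [im.label for im in images]
        est = NoduleCNNClassifier(variant="tiny", epochs=2, input_size=64,
                                  augment=False, batch_size=8)
        report = repeat_experiment(images, labels, n_repeats=2, master_seed=1,
                                   estimator=est)
        aucs = [r["auc"] for r in report.per_repeat]
        assert min(aucs) <= report.means["auc"] <= max(aucs)

    def test_invalid_repeat_count_rejected(self, small_dataset):
        images, _ = small_dataset
        with pytest.raises(ValueError):
            repeat_experiment(images, [im.label for im in images], n_repeats=0)
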