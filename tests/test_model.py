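"""Network topology, losses, gradients and training behaviour."""

import numpy as np
import pytest

from nanorevise.model import (ModelConfig, build_main_model, center_loss,
                              load_checkpoint, predict_events,
                              save_checkpoint, softmax_cross_entropy,
                              total_loss, train_model)
from nanorevise.windows import WindowSet


def tiny_config(num_classes=6, seed=0, **kw):
    defaults = dict(num_classes=num_classes, window=5, sig_cap=4,
                    conv_filters=4, read_branch_lstm_state=4,
                    trunk_lstm_state=6, trunk_lstm_layers=1, dense_units=8,
                    batch_size=8, epochs=3, seed=seed, feature_dim=7)
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_windows(n, cfg, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    sig = rng.normal(0, 1, size=(n, cfg.window * cfg.sig_cap)).astype(np.float32)
    feat = rng.normal(0, 1, size=(n, cfg.window, cfg.feature_dim)).astype(np.float32)
    y1 = rng.integers(0, cfg.num_classes, size=n)
    if separable:
        # plant the class label in the centre-position features
        for i in range(n):
            feat[i, cfg.window // 2, :] = 0.0
            feat[i, cfg.window // 2, y1[i] % cfg.feature_dim] = 3.0
            sig[i, :] = 0.1 * y1[i]
    y2 = y1 % 4
    return WindowSet(signal=sig, features=feat, labels1=y1.astype(np.int64),
                     labels2=y2.astype(np.int64), window=cfg.window,
                     sig_cap=cfg.sig_cap)


class TestTopology:
    def test_output_distribution_lengths(self):
        for ncls in (4, 6):
            cfg = tiny_config(num_classes=ncls)
            model = build_main_model(cfg)
            ws = random_windows(5, cfg)
            probs = predict_events(model, ws)
            assert probs.shape == (5, ncls)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(probs >= 0)

    def test_same_seed_same_initial_forward(self):
        cfg = tiny_config(seed=7)
        ws = random_windows(6, cfg, seed=1)
        a = build_main_model(cfg).predict_proba(ws.signal, ws.features)
        b = build_main_model(cfg).predict_proba(ws.signal, ws.features)
        np.testing.assert_array_equal(a, b)

    def test_residual_shortcut_is_live(self):
        cfg = tiny_config(seed=3)
        model = build_main_model(cfg)
        ws = random_windows(4, cfg, seed=2)
        base = model.predict_proba(ws.signal, ws.features)
        # zero the residual path of every block: output should change,
        # proving the shortcut carried signal around a live branch
        for blk in model.blocks:
            for p in blk.conv1.params() + blk.conv2.params():
                p.value[...] = 0.0
        ablated = model.predict_proba(ws.signal, ws.features)
        assert not np.allclose(base, ablated)

    def test_invalid_num_classes_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(num_classes=5)

    def test_batch_order_independence(self):
        cfg = tiny_config()
        model = build_main_model(cfg)
        ws = random_windows(10, cfg, seed=5)
        probs = predict_events(model, ws)
        perm = np.random.default_rng(0).permutation(10)
        ws2 = WindowSet(signal=ws.signal[perm], features=ws.features[perm],
                        window=cfg.window, sig_cap=cfg.sig_cap)
        probs2 = predict_events(model, ws2)
        np.testing.assert_allclose(probs2, probs[perm], atol=1e-6)

    def test_feature_dim_mismatch_rejected(self):
        cfg = tiny_config()
        model = build_main_model(cfg)
        bad = tiny_config(feature_dim=10)
        ws = random_windows(3, bad)
        with pytest.raises(ValueError, match="feature dimension"):
            predict_events(model, ws)


class TestLosses:
    def test_center_loss_zero_at_centers(self):
        centers = np.arange(12, dtype=float).reshape(3, 4)
        feats = centers[[0, 2, 1]]
        assert center_loss(feats, np.array([0, 2, 1]), centers) == 0.0

    def test_center_loss_single_sample(self):
        centers = np.zeros((2, 2))
        lc = center_loss(np.array([[3.0, 4.0]]), np.array([0]), centers)
        assert lc == pytest.approx(12.5)

    def test_center_loss_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(8, 5))
        centers = rng.normal(size=(6, 5))
        labels = rng.integers(0, 6, size=8)
        naive = 0.5 * sum(
            np.sum((feats[i] - centers[labels[i]]) ** 2) for i in range(8))
        assert center_loss(feats, labels, centers) == pytest.approx(
            naive, abs=1e-9)

    def test_center_loss_label_out_of_range(self):
        with pytest.raises(ValueError, match="center"):
            center_loss(np.zeros((1, 2)), np.array([5]), np.zeros((2, 2)))

    def test_total_loss_lambda_zero_is_cross_entropy(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(10, 6))
        labels = rng.integers(0, 6, size=10)
        feats = rng.normal(size=(10, 8))
        centers = rng.normal(size=(6, 8))
        # independent cross-entropy via explicit softmax
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        ce = -np.mean(np.log(p[np.arange(10), labels]))
        assert total_loss(logits, feats, labels, centers, 0.0) == \
            pytest.approx(ce, abs=1e-9)

    def test_uniform_logits_give_log_num_classes(self):
        for ncls in (4, 6):
            logits = np.zeros((7, ncls))
            labels = np.arange(7) % ncls
            ls, _ = softmax_cross_entropy(logits, labels)
            assert ls == pytest.approx(np.log(ncls), abs=1e-12)

    def test_total_loss_matches_naive_composition(self):
        rng = np.random.default_rng(2)
        m = 9
        logits = rng.normal(size=(m, 6))
        labels = rng.integers(0, 6, size=m)
        feats = rng.normal(size=(m, 8))
        centers = rng.normal(size=(6, 8))
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        ce = -np.mean(np.log(p[np.arange(m), labels]))
        lc = 0.5 * sum(np.sum((feats[i] - centers[labels[i]]) ** 2)
                       for i in range(m))
        expected = ce + 0.2 * lc / m
        assert total_loss(logits, feats, labels, centers, 0.2) == \
            pytest.approx(expected, abs=1e-9)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.zeros((1, 4)), np.zeros((1, 2)), np.array([0]),
                       np.zeros((4, 2)), -0.1)


class TestGradients:
    def test_finite_difference_check(self):
        """Analytic backprop through the full network agrees with central
        finite differences of the total loss on a 2-sample batch."""
        cfg = tiny_config(seed=5, dtype="float64", dropout_rate=0.0)
        model = build_main_model(cfg)
        ws = random_windows(2, cfg, seed=6)
        y = ws.labels1
        centers = np.random.default_rng(7).normal(size=model.centers.shape)
        model.centers = centers
        lam = cfg.lambda_center

        def loss():
            logits, penult = model.forward(ws.signal.astype(np.float64),
                                           ws.features.astype(np.float64),
                                           train=True)
            return total_loss(logits, penult, y, centers, lam)

        logits, penult = model.forward(ws.signal.astype(np.float64),
                                       ws.features.astype(np.float64),
                                       train=True)
        _, dlogits = softmax_cross_entropy(logits, y)
        dpenult = (lam / 2) * (penult - centers[y])
        for p in model.params():
            p.zero_grad()
        model.backward(dlogits, dpenult)

        rng = np.random.default_rng(8)
        eps = 1e-5
        checked = 0
        for p in model.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            idxs = rng.choice(flat.size, size=min(3, flat.size),
                              replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                # relative tolerance with an absolute floor for
                # zero-gradient parameters (finite-difference noise)
                assert abs(fd - gflat[i]) < \
                    1e-3 * max(abs(fd), abs(gflat[i])) + 1e-8, \
                    f"{p.name}[{i}]: fd={fd}, analytic={gflat[i]}"
                checked += 1
        assert checked > 30


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        cfg = tiny_config(seed=1, epochs=5)
        ws = random_windows(200, cfg, seed=2, separable=True)
        model = build_main_model(cfg)
        trace = train_model(model, ws)
        assert trace[-1]["total"] < trace[0]["total"]

    def test_overfit_probe_reaches_high_accuracy(self):
        cfg = tiny_config(seed=3, epochs=200, batch_size=32,
                          learning_rate=0.005, lr_decay=0.0)
        ws = random_windows(32, cfg, seed=4, separable=True)
        model = build_main_model(cfg)
        train_model(model, ws)
        probs = predict_events(model, ws)
        acc = np.mean(probs.argmax(axis=1) == ws.labels1)
        assert acc > 0.9

    def test_loss_trace_decomposition(self):
        cfg = tiny_config(seed=9, epochs=2)
        ws = random_windows(64, cfg, seed=9)
        model = build_main_model(cfg)
        trace = train_model(model, ws)
        for row in trace:
            assert row["total"] == pytest.approx(
                row["ls"] + cfg.lambda_center * row["lc"], abs=1e-6)

    def test_lambda_zero_is_plain_cross_entropy_training(self):
        # with lambda = 0 the reported total equals Ls exactly, and the
        # center term's gradient path is the only difference from a
        # lambda > 0 run
        cfg0 = tiny_config(seed=11, epochs=1, lambda_center=0.0)
        ws = random_windows(40, cfg0, seed=12)
        m0 = build_main_model(cfg0)
        trace0 = train_model(m0, ws)
        assert all(r["total"] == pytest.approx(r["ls"], abs=1e-12)
                   for r in trace0)
        cfg1 = tiny_config(seed=11, epochs=1, lambda_center=0.5)
        m1 = build_main_model(cfg1)
        train_model(m1, ws)
        diffs = [not np.allclose(p0.value, p1.value)
                 for p0, p1 in zip(m0.params(), m1.params())]
        assert any(diffs)

    def test_empty_training_set_rejected(self):
        cfg = tiny_config()
        ws = random_windows(4, cfg)
        ws.trainable = np.zeros(4, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            train_model(build_main_model(cfg), ws)

    def test_deterministic_given_seed(self):
        cfg = tiny_config(seed=13, epochs=2)
        ws = random_windows(50, cfg, seed=14)
        t1 = train_model(build_main_model(cfg), ws)
        t2 = train_model(build_main_model(cfg), ws)
        assert t1 == t2


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = tiny_config(seed=21, epochs=1)
        ws = random_windows(30, cfg, seed=22)
        model = build_main_model(cfg)
        train_model(model, ws)
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        loaded = load_checkpoint(str(path))
        np.testing.assert_array_equal(
            predict_events(loaded, ws), predict_events(model, ws))
        assert loaded.config == model.config
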