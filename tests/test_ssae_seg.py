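import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mptissue.ssae_seg as S
from mptissue.mpmri_io import MpMriStudy, normalize_channels
from mptissue.signatures import signature_sets_from_labels, sample_balanced
from mptissue.ssae_seg import (
    SaeLayer,
    SsaeModel,
    SsaeTrainConfig,
    fine_tune,
    kl_sparsity,
    pretrain_stack,
    sae_loss,
    satlin,
    segment_study,
    train_sae_layer,
    train_segmenter,
    train_softmax_head,
)


class TestSatlin:
    @pytest.mark.parametrize("x,expected", [(-0.5, 0.0), (0.0, 0.0),
                                            (0.3, 0.3), (1.0, 1.0),
                                            (1.7, 1.0)])
    def test_branch_table(self, x, expected):
        assert satlin(x) == expected

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_range_property(self, xs):
        out = satlin(np.array(xs))
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestKlSparsity:
    def test_zero_at_target(self):
        assert kl_sparsity(np.array([0.25, 0.25]), 0.25) == 0.0

    def test_closed_form_value(self):
        # 0.25*ln(0.25/0.5) + 0.75*ln(0.75/0.5)
        expected = 0.25 * np.log(0.5) + 0.75 * np.log(1.5)
        assert kl_sparsity(np.array([0.5]), 0.25) == pytest.approx(expected)
        assert kl_sparsity(np.array([0.5]), 0.25) == pytest.approx(0.1308, abs=1e-4)

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=10),
           st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_zero_iff_equal(self, rho_hat, rho):
        val = kl_sparsity(np.array(rho_hat), rho)
        assert val >= 0.0
        if any(abs(r - rho) > 1e-9 for r in rho_hat):
            assert val > 0.0
        else:
            assert val == pytest.approx(0.0, abs=1e-12)


def _finite_difference_grads(layer, X, cfg, h=1e-6):
    grads = []
    for arr in (layer.W_enc, layer.b_enc, layer.W_dec, layer.b_dec):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up = sae_loss(layer, X, cfg)
            arr[idx] = orig - h
            dn = sae_loss(layer, X, cfg)
            arr[idx] = orig
            g[idx] = (up - dn) / (2 * h)
        grads.append(g)
    return grads


class TestGradients:
    @pytest.mark.parametrize("activation", ["sigmoid", "satlin"])
    def test_analytic_matches_finite_differences(self, activation):
        rng = np.random.default_rng(0)
        cfg = SsaeTrainConfig(seed=0)
        for attempt in range(20):
            X = rng.uniform(0.1, 0.9, size=(6, 4))
            layer = SaeLayer(
                W_enc=rng.normal(0, 0.4, (3, 4)),
                b_enc=rng.uniform(0.2, 0.4, 3),
                W_dec=rng.normal(0, 0.4, (4, 3)),
                b_dec=rng.normal(0, 0.1, 4),
                activation=activation,
            )
            Z = X @ layer.W_enc.T + layer.b_enc
            if activation == "satlin" and (
                    np.min(np.abs(Z)) < 1e-3 or np.min(np.abs(Z - 1)) < 1e-3):
                continue  # resample away from the satlin kinks
            analytic = S._sae_grads(layer, X, cfg)
            numeric = _finite_difference_grads(layer, X, cfg)
            for a, n in zip(analytic, numeric):
                np.testing.assert_allclose(a, n, rtol=1e-5, atol=1e-7)
            return
        pytest.fail("could not sample a kink-free satlin instance")


class TestTrainSaeLayer:
    def test_degenerate_dataset_reconstructed(self):
        v = np.array([0.2, 0.6, 0.4, 0.8])
        X = np.tile(v, (200, 1))
        cfg = SsaeTrainConfig(sparsity_weight=0.0, l2_penalty=0.0,
                              max_epochs=3000, learning_rate=0.3, seed=1)
        layer = train_sae_layer(X, 3, cfg)
        err = np.abs(layer.decode(layer.encode(X)) - X).max()
        assert err < 1e-3

    def test_seeded_determinism(self, tiny_training_set, fast_cfg):
        X = tiny_training_set.signatures
        a = train_sae_layer(X, 10, fast_cfg)
        b = train_sae_layer(X, 10, fast_cfg)
        np.testing.assert_array_equal(a.W_enc, b.W_enc)
        np.testing.assert_array_equal(a.W_dec, b.W_dec)

    def test_sparsity_penalty_pulls_activations_to_target(
            self, tiny_training_set):
        X = tiny_training_set.signatures
        with_pen = train_sae_layer(
            X, 10, SsaeTrainConfig(sparsity_weight=4.0, max_epochs=200, seed=2))
        without = train_sae_layer(
            X, 10, SsaeTrainConfig(sparsity_weight=0.0, max_epochs=200, seed=2))
        gap_with = np.abs(with_pen.encode(X).mean(axis=0) - 0.25).mean()
        gap_without = np.abs(without.encode(X).mean(axis=0) - 0.25).mean()
        assert gap_with < gap_without

    def test_loss_not_worse_than_init(self, tiny_training_set, fast_cfg):
        X = tiny_training_set.signatures
        layer = train_sae_layer(X, 10, fast_cfg)
        rng = np.random.default_rng(fast_cfg.seed)
        init = SaeLayer(W_enc=S._init_weights(10, X.shape[1], rng),
                        b_enc=np.full(10, fast_cfg.sparsity_proportion),
                        W_dec=S._init_weights(X.shape[1], 10, rng),
                        b_dec=np.zeros(X.shape[1]))
        assert sae_loss(layer, X, fast_cfg) <= sae_loss(init, X, fast_cfg)

    def test_too_few_rows_rejected(self, fast_cfg):
        with pytest.raises(ValueError):
            train_sae_layer(np.ones((5, 4)), 10, fast_cfg)


class TestStackAndHead:
    def test_stack_dimensions(self, tiny_training_set, fast_cfg):
        layers = pretrain_stack(tiny_training_set.signatures, fast_cfg)
        dims = [layers[0].d_in] + [l.d_out for l in layers]
        assert dims == [13, 10, 10, 10, 10, 10]

    def test_encodings_in_unit_interval(self, tiny_training_set, fast_cfg):
        layers = pretrain_stack(tiny_training_set.signatures, fast_cfg)
        H = tiny_training_set.signatures
        for layer in layers:
            H = layer.encode(H)
            assert H.min() >= 0.0 and H.max() <= 1.0

    def test_distinct_class_means_encode_distinctly(self, noiseless_phantom,
                                                    fast_cfg):
        study = normalize_channels(noiseless_phantom.study, method="minmax")
        sets = signature_sets_from_labels(study, noiseless_phantom.truth_labels,
                                          max_per_class=100, seed=0)
        train = sample_balanced(sets, cap_per_class=100, seed=0)
        layers = pretrain_stack(train.signatures, fast_cfg)
        means = []
        for cid in range(4):
            H = train.signatures[train.labels == cid][:1]
            for layer in layers:
                H = layer.encode(H)
            means.append(H[0])
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.allclose(means[i], means[j])

    def test_softmax_separable_clusters(self, fast_cfg):
        rng = np.random.default_rng(0)
        centers = np.eye(4).repeat(3, axis=1)[:, :10] * 0.9
        H = np.vstack([c + rng.normal(0, 0.01, (30, 10)) for c in centers])
        y = np.repeat(np.arange(4), 30)
        W, b = train_softmax_head(H, y, fast_cfg)
        model = SsaeModel(layers=[], softmax_W=W, softmax_b=b)
        probs = S._softmax(H @ W.T + b)
        assert (np.argmax(probs, axis=1) == y).mean() == 1.0

    def test_softmax_probs_sum_to_one(self, fast_cfg):
        rng = np.random.default_rng(1)
        H = rng.random((50, 10))
        y = rng.integers(0, 4, 50)
        y[:4] = [0, 1, 2, 3]
        W, b = train_softmax_head(H, y, fast_cfg)
        probs = S._softmax(rng.random((7, 10)) @ W.T + b)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_softmax_rejects_missing_class(self, fast_cfg):
        with pytest.raises(ValueError, match="missing"):
            train_softmax_head(np.random.default_rng(0).random((20, 10)),
                               np.zeros(20, dtype=int), fast_cfg)

    def test_row_permutation_leaves_predictions(self, fast_cfg):
        rng = np.random.default_rng(2)
        H = rng.random((40, 10))
        y = np.repeat(np.arange(4), 10)
        W1, b1 = train_softmax_head(H, y, fast_cfg)
        perm = rng.permutation(40)
        W2, b2 = train_softmax_head(H[perm], y[perm], fast_cfg)
        p1 = np.argmax(H @ W1.T + b1, axis=1)
        p2 = np.argmax(H @ W2.T + b2, axis=1)
        np.testing.assert_array_equal(p1, p2)


class TestFineTune:
    def _model(self, training, cfg):
        layers = pretrain_stack(training.signatures, cfg)
        H = training.signatures
        for layer in layers:
            H = layer.encode(H)
        W, b = train_softmax_head(H, training.labels, cfg)
        return SsaeModel(layers=layers, softmax_W=W, softmax_b=b)

    def test_disabled_returns_model_unchanged(self, tiny_training_set,
                                              fast_cfg):
        cfg = replace(fast_cfg, fine_tune=False)
        model = self._model(tiny_training_set, cfg)
        W_before = model.softmax_W.copy()
        out = fine_tune(model, tiny_training_set.signatures,
                        tiny_training_set.labels, cfg)
        np.testing.assert_array_equal(out.softmax_W, W_before)

    def test_loss_not_worse(self, tiny_training_set, fast_cfg):
        model = self._model(tiny_training_set, fast_cfg)
        X, y = tiny_training_set.signatures, tiny_training_set.labels
        N = len(y)
        Y = np.zeros((N, 4))
        Y[np.arange(N), y] = 1.0
        before = S._ce_loss(model, X, Y, fast_cfg.l2_penalty)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fine_tune(model, X, y, fast_cfg)
        after = S._ce_loss(model, X, Y, fast_cfg.l2_penalty)
        assert after <= before + 1e-12

    def test_seeded_reproducibility(self, tiny_training_set, fast_cfg):
        m1 = self._model(tiny_training_set, fast_cfg)
        m2 = self._model(tiny_training_set, fast_cfg)
        X, y = tiny_training_set.signatures, tiny_training_set.labels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = fine_tune(m1, X, y, fast_cfg)
            m2 = fine_tune(m2, X, y, fast_cfg)
        np.testing.assert_array_equal(m1.softmax_W, m2.softmax_W)
        for l1, l2 in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(l1.W_enc, l2.W_enc)


class TestSegmentStudy:
    def test_noiseless_phantom_high_accuracy(self, noiseless_phantom):
        study = normalize_channels(noiseless_phantom.study, method="minmax")
        sets = signature_sets_from_labels(study, noiseless_phantom.truth_labels,
                                          max_per_class=200, seed=0)
        train = sample_balanced(sets, cap_per_class=200, seed=0)
        # full-length training: the degenerate noiseless set (one distinct
        # vector per class) needs the complete head/fine-tune schedule
        model = train_segmenter(train, SsaeTrainConfig(seed=0),
                                channel_order=study.channel_order)
        seg = segment_study(model, study)
        acc = (seg.labels == noiseless_phantom.truth_labels.labels).mean()
        assert acc > 0.99

    def test_zero_study_constant_map(self, tiny_training_set, fast_cfg):
        model = train_segmenter(tiny_training_set, fast_cfg)
        zeros = MpMriStudy(
            channels={f"c{i}": np.zeros((4, 4, 2)) for i in range(13)},
            channel_order=[f"c{i}" for i in range(13)])
        seg = segment_study(model, zeros)
        assert len(np.unique(seg.labels)) == 1

    def test_legend(self, tiny_training_set, fast_cfg):
        model = train_segmenter(tiny_training_set, fast_cfg)
        assert model.class_legend == {0: "background", 1: "fat",
                                      2: "glandular", 3: "lesion"}

    def test_dimension_mismatch_rejected(self, tiny_training_set, fast_cfg):
        model = train_segmenter(tiny_training_set, fast_cfg)
        bad = MpMriStudy(channels={"a": np.zeros((3, 3, 2)),
                                   "b": np.zeros((3, 3, 2))},
                         channel_order=["a", "b"])
        with pytest.raises(ValueError):
            segment_study(model, bad)

    def test_channel_order_mismatch_rejected(self, tiny_training_set,
                                             fast_cfg, tiny_normalized):
        model = train_segmenter(tiny_training_set, fast_cfg,
                                channel_order=tiny_normalized[0].channel_order)
        st = tiny_normalized[0]
        scrambled = MpMriStudy(channels=dict(st.channels),
                               channel_order=list(reversed(st.channel_order)),
                               voxel_spacing=st.voxel_spacing)
        with pytest.raises(ValueError, match="channel order"):
            segment_study(model, scrambled)


class TestModelSerialization:
    def test_round_trip(self, tiny_training_set, fast_cfg, tmp_path):
        model = train_segmenter(tiny_training_set, fast_cfg)
        model.save(tmp_path / "m.json")
        loaded = SsaeModel.load(tmp_path / "m.json")
        X = tiny_training_set.signatures[:5]
        np.testing.assert_allclose(loaded.predict_proba(X),
                                   model.predict_proba(X), atol=1e-12)

    def test_satlin_range_property_random_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            layer = SaeLayer(W_enc=rng.normal(0, 2, (10, 6)),
                             b_enc=rng.normal(0, 2, 10),
                             W_dec=np.zeros((6, 10)), b_dec=np.zeros(6))
            H = layer.encode(rng.normal(0, 3, (20, 6)))
            assert H.min() >= 0.0 and H.max() <= 1.0
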