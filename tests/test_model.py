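"""Network algebra, gradients, and training behavior."""

import numpy as np
import pytest

from ppii.dataset import make_all_windows, split, undersample_balance
from ppii.errors import ConfigError, InputError
from ppii.fixtures import MotifSpec, make_labeled_sequences
from ppii.model import (CNNConfig, EncoderConfig, PPIIClassifier, TrainConfig,
                        conv_channel, fuse_and_classify, local_features,
                        position_encoding, position_encoding_matrix,
                        residual_then_norm, self_attention, softmax, train,
                        windows_to_tokens)


class TestPositionEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = position_encoding(0, 8)
        assert np.allclose(pe, [0, 1] * 4)

    def test_direct_evaluation_at_position_one(self):
        pe = position_encoding(1, 4)
        assert pe[0] == pytest.approx(np.sin(1.0))
        assert pe[1] == pytest.approx(np.cos(1.0))
        assert pe[2] == pytest.approx(np.sin(1.0 / 10000.0 ** (2 / 4)))
        assert pe[3] == pytest.approx(np.cos(1.0 / 10000.0 ** (2 / 4)))

    def test_positions_are_distinct(self):
        mat = position_encoding_matrix(101, 8)
        assert len({tuple(np.round(row, 12)) for row in mat}) == 101

    def test_values_bounded_by_one(self):
        mat = position_encoding_matrix(50, 16)
        assert np.all(np.abs(mat) <= 1.0)


class TestEmbedding:
    def test_zero_embedding_table_gives_pure_position_code(self):
        model = PPIIClassifier(EncoderConfig.tiny(n_layers=0),
                               CNNConfig.tiny(), seed=0)
        model.params["emb"][:] = 0.0
        tokens = windows_to_tokens(["ACDEFGHKLMNPQRS"])[0]
        x = model.embed(tokens)
        assert np.allclose(x, position_encoding_matrix(16, 32))

    def test_shape_contract(self):
        model = PPIIClassifier(EncoderConfig.tiny(), CNNConfig.tiny(), seed=0)
        x = model.embed(windows_to_tokens(["ACDEFGHKLMNPQRS"]))
        assert x.shape == (1, 16, 32)

    def test_single_residue_change_is_local_before_attention(self):
        model = PPIIClassifier(EncoderConfig.tiny(), CNNConfig.tiny(), seed=0)
        a = model.embed(windows_to_tokens(["AAAAAAA"])[0])
        b = model.embed(windows_to_tokens(["AAAWAAA"])[0])
        diff_rows = np.where(np.any(a != b, axis=1))[0]
        assert list(diff_rows) == [4]  # CLS shifts rows by one

    def test_unknown_token_rejected(self):
        with pytest.raises(InputError):
            windows_to_tokens(["ACDEZ"])


class TestSelfAttention:
    def test_single_token_returns_its_value_projection(self, rng):
        d = 8
        x = rng.normal(size=(1, d))
        wq, wk, wv = rng.normal(size=(3, d, d))
        out = self_attention(x, wq, wk, wv)
        assert np.allclose(out, x @ wv)

    def test_attention_rows_sum_to_one(self, rng):
        x = rng.normal(size=(9, 16))
        wq, wk, wv = rng.normal(size=(3, 16, 16))
        _, weights = self_attention(x, wq, wk, wv, n_heads=4,
                                    return_weights=True)
        assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_query_key_gives_uniform_average_of_values(self, rng):
        x = rng.normal(size=(7, 8))
        wv = rng.normal(size=(8, 8))
        zeros = np.zeros((8, 8))
        out = self_attention(x, zeros, zeros, wv)
        v = x @ wv
        assert np.allclose(out, np.tile(v.mean(axis=0), (7, 1)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ConfigError):
            self_attention(rng.normal(size=(3, 4)),
                           rng.normal(size=(5, 5)),
                           rng.normal(size=(5, 5)),
                           rng.normal(size=(5, 5)))


class TestResidualThenNorm:
    def test_zero_sublayer_normalizes_input_alone(self, rng):
        x = rng.normal(size=(4, 16))
        out = residual_then_norm(x, np.zeros_like(x))
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        assert np.allclose(out, (x - mu) / (sd + 1e-12), atol=1e-9)

    def test_constant_row_maps_to_beta(self):
        x = np.full((2, 8), 3.5)
        beta = np.full(8, -0.25)
        out = residual_then_norm(x, np.zeros_like(x), beta=beta)
        assert np.allclose(out, -0.25)

    def test_pre_affine_rows_are_standardized(self, rng):
        x = rng.normal(size=(6, 32))
        sub = rng.normal(size=(6, 32))
        out = residual_then_norm(x, sub)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-5)
        assert np.allclose(out.std(axis=1), 1.0, atol=1e-5)


def brute_force_conv(tokmat, weights, bias):
    """Sliding dot-product oracle over explicit windows."""
    n, d = tokmat.shape
    md, q = weights.shape
    m = md // d
    pooled = np.full(q, -np.inf)
    for i in range(n - m + 1):
        patch = tokmat[i:i + m].reshape(-1)
        c = patch @ weights + bias
        pooled = np.maximum(pooled, c)
    return pooled


class TestConvChannel:
    def test_feature_map_length_is_n_minus_m_plus_one(self, rng):
        n, d, m, q = 13, 6, 3, 4
        tok = rng.normal(size=(n, d))
        w = rng.normal(size=(m * d, q))
        b = rng.normal(size=q)
        from ppii.model import _conv_maps
        maps = _conv_maps(tok[None], w, b, m)
        assert maps.shape == (1, n - m + 1, q)

    def test_zero_weights_pool_to_bias(self, rng):
        tok = rng.normal(size=(8, 4))
        b = np.array([0.5, -1.0])
        out = conv_channel(tok, np.zeros((12, 2)), b)
        assert np.allclose(out, b)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 11))
            d = int(rng.integers(2, 7))
            m = int(rng.integers(1, n + 1))
            q = int(rng.integers(1, 5))
            tok = rng.normal(size=(n, d))
            w = rng.normal(size=(m * d, q))
            b = rng.normal(size=q)
            assert np.allclose(conv_channel(tok, w, b),
                               brute_force_conv(tok, w, b), atol=1e-9)

    def test_kernel_larger_than_sequence_rejected(self, rng):
        with pytest.raises(ConfigError):
            conv_channel(rng.normal(size=(3, 4)),
                         rng.normal(size=(16, 2)), np.zeros(2))


class TestLocalFeaturesAndFusion:
    @staticmethod
    def conv_params(rng, kernels, d, q):
        return {f"conv{m}.W": rng.normal(size=(m * d, q))
                for m in kernels} | \
               {f"conv{m}.b": rng.normal(size=q) for m in kernels}

    def test_concatenation_length_and_order(self, rng):
        d, q = 5, 3
        params = self.conv_params(rng, (2, 3, 4), d, q)
        tok = rng.normal(size=(10, d))
        eta = local_features(tok, params, (2, 3, 4))
        assert eta.shape == (9,)
        # permutation covariance with declared kernel order
        eta_rev = local_features(tok, params, (4, 3, 2))
        assert np.allclose(eta_rev,
                           np.concatenate([eta[6:], eta[3:6], eta[:3]]))

    def test_single_kernel_equals_conv_channel(self, rng):
        d, q = 4, 2
        params = self.conv_params(rng, (3,), d, q)
        tok = rng.normal(size=(8, d))
        assert np.allclose(local_features(tok, params, (3,)),
                           conv_channel(tok, params["conv3.W"],
                                        params["conv3.b"]))

    def test_probabilities_sum_to_one(self, rng):
        cls = rng.normal(size=16)
        eta = rng.normal(size=6)
        w = rng.normal(size=(22, 2))
        probs = fuse_and_classify(cls, eta, w, rng.normal(size=2))
        assert probs.sum() == pytest.approx(1.0, abs=1e-7)
        assert np.all((probs > 0) & (probs < 1))

    def test_zero_classifier_gives_uniform(self, rng):
        probs = fuse_and_classify(rng.normal(size=4), rng.normal(size=2),
                                  np.zeros((6, 2)), np.zeros(2))
        assert np.allclose(probs, 0.5)

    def test_fused_dimension_is_dmodel_plus_q_times_kernels(self):
        model = PPIIClassifier(
            EncoderConfig.tiny(), CNNConfig(kernel_sizes=(3, 4, 5),
                                            filters_q=16), seed=0)
        assert model.fused_dim == 32 + 3 * 16
        assert model.params["clf.W"].shape[0] == model.fused_dim
        big = PPIIClassifier(
            EncoderConfig.tiny(d_model=768, n_heads=12, n_layers=0,
                               d_ff=64),
            CNNConfig(kernel_sizes=(3, 4, 5), filters_q=64), seed=0)
        assert big.fused_dim == 768 + 3 * 64


class TestEncode:
    def test_output_shapes(self):
        model = PPIIClassifier(EncoderConfig.tiny(), CNNConfig.tiny(), seed=0)
        enc = model.encode(windows_to_tokens(["ACDEFGHKLMNPQRS"])[0])
        assert enc.cls_vector.shape == (32,)
        assert enc.token_matrix.shape == (15, 32)

    def test_zero_layer_stack_returns_embedded_cls(self):
        model = PPIIClassifier(EncoderConfig.tiny(n_layers=0),
                               CNNConfig.tiny(), seed=0)
        tokens = windows_to_tokens(["ACDEFGHKLMNPQRS"])[0]
        enc = model.encode(tokens)
        assert np.allclose(enc.cls_vector, model.embed(tokens)[0])

    def test_position_encoding_breaks_permutation_invariance(self, rng):
        model = PPIIClassifier(EncoderConfig.tiny(), CNNConfig.tiny(), seed=0)
        for _ in range(5):
            win = list(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 15))
            win2 = list(win)
            win2[1], win2[12] = win2[12], win2[1]
            if win2 == win:
                continue
            a = model.encode(windows_to_tokens(["".join(win)])[0])
            b = model.encode(windows_to_tokens(["".join(win2)])[0])
            assert not np.allclose(a.cls_vector, b.cls_vector)

    def test_window_longer_than_max_len_rejected(self):
        model = PPIIClassifier(EncoderConfig.tiny(max_len=8),
                               CNNConfig.tiny(), seed=0)
        with pytest.raises(InputError):
            model.encode(windows_to_tokens(["ACDEFGHKLMNPQRS"])[0])


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        enc = EncoderConfig.tiny(d_model=16, n_heads=2, n_layers=2,
                                 d_ff=24, max_len=16)
        cnn = CNNConfig(kernel_sizes=(2, 3), filters_q=3)
        model = PPIIClassifier(enc, cnn, seed=0)
        tokens = rng.integers(0, 21, size=(4, 9))
        labels = np.array([0, 1, 1, 0])
        _, grads = model.loss_and_grads(tokens, labels)
        h = 1e-6
        check_rng = np.random.default_rng(2)
        for name, p in model.params.items():
            flat = p.reshape(-1)
            idxs = check_rng.choice(flat.size, size=min(6, flat.size),
                                    replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + h
                lp = model.loss(tokens, labels)
                flat[i] = orig - h
                lm = model.loss(tokens, labels)
                flat[i] = orig
                num = (lp - lm) / (2 * h)
                ana = grads[name].reshape(-1)[i]
                rel = abs(num - ana) / max(abs(num) + abs(ana), 1e-3)
                assert rel < 1e-4, f"{name}[{i}]: {num} vs {ana}"


@pytest.fixture(scope="module")
def training_run(balanced_split_small, tiny_encoder, tiny_cnn):
    return train(balanced_split_small, tiny_encoder, tiny_cnn,
                 TrainConfig(epochs=5, seed=11))


class TestTraining:
    def test_loss_decreases_on_separable_data(self, training_run):
        _, log = training_run
        losses = [row["train_loss"] for row in log[:3]]
        assert losses[0] > losses[1] > losses[2]

    def test_validation_auc_reaches_high_discrimination(self, training_run):
        _, log = training_run
        assert max(row["val_auc"] for row in log) >= 0.9

    def test_fixed_seed_reproduces_epoch_one_loss(self, balanced_split_small,
                                                  tiny_encoder, tiny_cnn):
        cfg = TrainConfig(epochs=1, seed=21)
        _, log_a = train(balanced_split_small, tiny_encoder, tiny_cnn, cfg)
        _, log_b = train(balanced_split_small, tiny_encoder, tiny_cnn, cfg)
        assert log_a[0]["train_loss"] == log_b[0]["train_loss"]
        assert log_a[0]["val_auc"] == log_b[0]["val_auc"]

    def test_label_shuffled_control_is_chance_level(self):
        seqs = make_labeled_sequences(MotifSpec(n_sequences=220, seed=17))
        windows = make_all_windows(seqs, 15)
        balanced = undersample_balance(windows, seed=3)
        rng = np.random.default_rng(5)
        labels = np.array([s.label for s in balanced])
        rng.shuffle(labels)
        for s, y in zip(balanced, labels):
            s.label = int(y)
        rng2 = np.random.default_rng(6)
        idx = rng2.choice(len(balanced), min(2000, len(balanced)),
                          replace=False)
        subset = [balanced[i] for i in idx]
        ds = split(subset, "balanced_4to1", seed=9)
        _, log = train(ds, EncoderConfig.tiny(), CNNConfig.tiny(),
                       TrainConfig(epochs=4, seed=13))
        final_auc = log[-1]["val_auc"]
        assert 0.4 <= final_auc <= 0.6

    def test_save_load_round_trip_preserves_predictions(self, training_run,
                                                        tmp_path,
                                                        balanced_split_small):
        model, _ = training_run
        before = model.predict_samples(balanced_split_small.val[:50])
        model.save(tmp_path / "run")
        reloaded = PPIIClassifier.load(tmp_path / "run")
        after = reloaded.predict_samples(balanced_split_small.val[:50])
        assert np.allclose(before, after)


class TestSoftmaxUtility:
    def test_rows_normalize(self, rng):
        x = rng.normal(size=(5, 7)) * 10
        s = softmax(x, axis=-1)
        assert np.allclose(s.sum(axis=-1), 1.0)
        assert np.all(s > 0)
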