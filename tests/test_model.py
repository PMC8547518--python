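"""Attention classifier: oracle equivalence, softmax conservation, training."""

import numpy as np
import pytest

import morphattn as m
from morphattn._autograd import Tensor
from morphattn.model import (
    AttentionLayerParams,
    ModelConfig,
    attention_layer_forward,
    init_model,
    model_forward,
    predict,
    train_model,
)


def make_params(rng, d_in, d_out, n_heads=1):
    d_k = d_out // n_heads
    t = lambda: Tensor(rng.normal(size=(d_k, d_in)), requires_grad=True)
    return AttentionLayerParams(
        W_Q=[t() for _ in range(n_heads)],
        W_K=[t() for _ in range(n_heads)],
        W_V=[t() for _ in range(n_heads)],
    )


def naive_attention(X, params):
    """Literal loop evaluation: queries/keys/values, scores, softmax, sums."""
    M = X.shape[0]
    n_heads = params.n_heads
    d_k = params.d_k
    Y_heads, alphas = [], []
    for h in range(n_heads):
        Wq, Wk, Wv = params.W_Q[h].data, params.W_K[h].data, params.W_V[h].data
        Q = [Wq @ X[p] for p in range(M)]
        K = [Wk @ X[p] for p in range(M)]
        V = [Wv @ X[p] for p in range(M)]
        alpha = np.zeros((M, M))
        for p in range(M):
            scores = np.array([np.dot(Q[p], K[q]) / np.sqrt(d_k)
                               for q in range(M)])
            e = np.exp(scores - scores.max())
            alpha[p] = e / e.sum()
        Y = np.zeros((M, d_k))
        for p in range(M):
            for q in range(M):
                Y[p] += alpha[p, q] * V[q]
        Y_heads.append(Y)
        alphas.append(alpha)
    return np.concatenate(Y_heads, axis=1), np.mean(alphas, axis=0)


class TestAttentionLayer:
    def test_hand_sized_instance_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = np.array([[1.0, 2.0], [0.0, -1.0], [3.0, 0.5]])
        params = AttentionLayerParams(
            W_Q=[Tensor(np.array([[1.0, 0.0], [0.0, 2.0]]))],
            W_K=[Tensor(np.array([[0.0, 1.0], [1.0, 1.0]]))],
            W_V=[Tensor(np.array([[2.0, 0.0], [1.0, -1.0]]))],
        )
        Y, alpha = attention_layer_forward(X, params)
        Y_ref, alpha_ref = naive_attention(X, params)
        np.testing.assert_allclose(alpha, alpha_ref, atol=1e-10)
        np.testing.assert_allclose(Y, Y_ref, atol=1e-10)

    @pytest.mark.parametrize("M,d_in,d_out,n_heads", [
        (3, 2, 2, 1), (5, 4, 4, 2), (4, 3, 4, 4), (2, 4, 4, 1),
    ])
    def test_random_instances_match_loop_oracle(self, M, d_in, d_out, n_heads,
                                                rng):
        X = rng.normal(size=(M, d_in))
        params = make_params(rng, d_in, d_out, n_heads)
        Y, alpha = attention_layer_forward(X, params)
        Y_ref, alpha_ref = naive_attention(X, params)
        np.testing.assert_allclose(alpha, alpha_ref, atol=1e-10)
        np.testing.assert_allclose(Y, Y_ref, atol=1e-10)

    @pytest.mark.parametrize("n_heads", [1, 2, 4])
    def test_alpha_rows_sum_to_one(self, n_heads, rng):
        X = rng.normal(size=(6, 4))
        params = make_params(rng, 4, 4, n_heads)
        _, alpha = attention_layer_forward(X, params)
        np.testing.assert_allclose(alpha.sum(axis=1), np.ones(6), atol=1e-6)

    def test_zero_query_weights_give_exactly_uniform_alpha(self, rng):
        M = 5
        X = rng.normal(size=(M, 3))
        params = make_params(rng, 3, 2)
        params.W_Q[0].data[:] = 0.0
        Y, alpha = attention_layer_forward(X, params)
        np.testing.assert_array_equal(alpha, np.full((M, M), 1.0 / M))
        V = X @ params.W_V[0].data.T
        np.testing.assert_allclose(Y, np.tile(V.mean(axis=0), (M, 1)),
                                   atol=1e-12)

    def test_token_permutation_equivariance(self, rng):
        """Reordering the region rows permutes alpha rows and columns alike."""
        X = rng.normal(size=(6, 4))
        params = make_params(rng, 4, 4)
        perm = rng.permutation(6)
        _, alpha = attention_layer_forward(X, params)
        _, alpha_p = attention_layer_forward(X[perm], params)
        np.testing.assert_allclose(alpha_p, alpha[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_non_finite_input_rejected(self, rng):
        params = make_params(rng, 2, 2)
        with pytest.raises(ValueError, match="finite"):
            attention_layer_forward(np.array([[np.nan, 1.0]]), params)


class TestModelConfig:
    def test_defaults_reproduce_published_recipe(self):
        cfg = ModelConfig()
        assert (cfg.n_attention_layers, cfg.n_heads, cfg.d_embed) == (2, 1, 32)
        assert cfg.leaky_slope == 1e-2
        assert cfg.learning_rate == 6e-6
        assert (cfg.batch_size, cfg.weight_decay) == (32, 0.01)

    @pytest.mark.parametrize("bad", [dict(n_heads=3), dict(n_attention_layers=6),
                                     dict(n_heads=8, d_embed=31)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)

    @pytest.mark.parametrize("n_heads", [1, 2, 4, 8])
    def test_parameter_count_independent_of_heads(self, n_heads):
        model = init_model(ModelConfig(n_heads=n_heads), M=20)
        ref = init_model(ModelConfig(n_heads=1), M=20)
        assert model.n_parameters() == ref.n_parameters()


class TestModelForward:
    def test_zero_head_weights_give_exactly_half(self, small_networks):
        model = init_model(ModelConfig(d_embed=8, seed=0),
                           M=small_networks[0].M)
        model.W2.data[:] = 0.0
        model.b2.data[:] = 0.0
        record = model_forward(small_networks[0], model)
        assert record.probability == 0.5

    def test_evaluation_mode_is_deterministic(self, small_networks,
                                              tiny_trained_model):
        a = model_forward(small_networks[0], tiny_trained_model)
        b = model_forward(small_networks[0], tiny_trained_model)
        assert a.probability == b.probability
        for x, y in zip(a.alpha, b.alpha):
            np.testing.assert_array_equal(x, y)

    def test_alpha_rows_stochastic_per_layer(self, small_networks,
                                             tiny_trained_model):
        record = model_forward(small_networks[0], tiny_trained_model)
        assert len(record.alpha) == 2
        for alpha in record.alpha:
            np.testing.assert_allclose(alpha.sum(axis=1),
                                       np.ones(alpha.shape[0]), atol=1e-6)

    def test_region_count_mismatch_rejected(self, tiny_trained_model, rng):
        wrong = m.MorphNetwork(X=np.ones((3, 3)), region_labels=[0, 1, 2])
        with pytest.raises(ValueError, match="regions"):
            model_forward(wrong, tiny_trained_model)


class TestTraining:
    def test_same_seed_gives_identical_weights(self, small_networks,
                                               small_effect_cohort):
        cfg = ModelConfig(d_embed=8, max_epochs=10, learning_rate=1e-2,
                          weight_decay=0.0, seed=5)
        y = small_effect_cohort.labels
        m1 = train_model(small_networks, y, cfg)
        m2 = train_model(small_networks, y, cfg)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_separable_cohort_reaches_high_training_accuracy(
            self, small_networks, small_effect_cohort):
        cfg = ModelConfig(max_epochs=200, learning_rate=1e-2,
                          weight_decay=0.0, seed=1)
        y = small_effect_cohort.labels
        model = train_model(small_networks, y, cfg)
        preds = [predict(model, net)[0] for net in small_networks]
        assert np.mean(np.array(preds) == y) >= 0.95
        losses = model.train_log["loss"]
        assert losses[-1] <= losses[0]

    def test_single_class_rejected(self, small_networks):
        cfg = ModelConfig(d_embed=8, max_epochs=2)
        with pytest.raises(ValueError, match="class"):
            train_model(small_networks, np.ones(len(small_networks)), cfg)


class TestPredict:
    def test_threshold_conventions(self, small_networks, tiny_trained_model):
        label, prob = predict(tiny_trained_model, small_networks[0],
                              threshold=0.5)
        assert label == int(prob >= 0.5)
        # probability exactly at the threshold counts positive
        assert predict(tiny_trained_model, small_networks[0],
                       threshold=prob)[0] == 1

    def test_out_of_range_threshold_rejected(self, small_networks,
                                             tiny_trained_model):
        with pytest.raises(ValueError, match="threshold"):
            predict(tiny_trained_model, small_networks[0], threshold=1.1)


def test_save_load_round_trip(tmp_path, small_networks, tiny_trained_model):
    path = tmp_path / "model.json"
    m.save_model(tiny_trained_model, path)
    loaded = m.load_model(path)
    a = model_forward(small_networks[0], tiny_trained_model)
    b = model_forward(small_networks[0], loaded)
    assert a.probability == b.probability
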