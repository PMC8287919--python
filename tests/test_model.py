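import math

import numpy as np
import pytest

from attnteract.autodiff import Tensor
from attnteract.model import (Model, ModelConfig, attention_head, combine_heads,
                              loss_binary, loss_multilabel, lstm_layer)
from attnteract.seqdata import Sequence, one_hot_encode

from conftest import random_onehot


# ---------------------------------------------------------------- convolution
def conv_oracle(x, w):
    """Direct double-sum evaluation of the valid 1-D convolution."""
    f, _, a = w.shape
    lout = x.shape[1] - a + 1
    out = np.zeros((f, lout))
    for j in range(f):
        for i in range(lout):
            out[j, i] = sum(w[j, b, k] * x[b, i + k]
                            for k in range(a) for b in range(4))
    return out


def test_conv_matches_two_loop_oracle(rng):
    x = random_onehot(rng, 1, 12)[0]
    w = rng.standard_normal((3, 4, 5))
    got = Tensor(x[None]).conv1d(Tensor(w)).data[0]
    np.testing.assert_allclose(got, conv_oracle(x, w), atol=1e-12)


def test_conv_ac_filter_scanned_over_aacg():
    """One-hot "AC" filter over "AACG": windows AA, AC, CG -> [1, 2, 0]."""
    x = one_hot_encode(Sequence("s", "AACG"))
    w = one_hot_encode(Sequence("f", "AC"))[None]        # filter = one-hot of "AC"
    got = Tensor(x[None]).conv1d(Tensor(w)).data[0, 0]
    np.testing.assert_array_equal(got, conv_oracle(x, w)[0])
    np.testing.assert_array_equal(got, [1.0, 2.0, 0.0])


def test_all_zero_filter_gives_zero_map(rng):
    x = random_onehot(rng, 2, 10)
    out = Tensor(x).conv1d(Tensor(np.zeros((2, 4, 3)))).data
    assert not out.any()


# ----------------------------------------------------------------- max pool
def test_max_pool_window_one_is_identity(rng):
    x = Tensor(rng.standard_normal((1, 2, 7)))
    np.testing.assert_array_equal(x.max_pool1d(1).data, x.data)


def test_max_pool_direct_oracle():
    row = Tensor(np.array([[[1.0, 5.0, 2.0, 0.0]]]))
    np.testing.assert_array_equal(row.max_pool1d(2).data, [[[5.0, 2.0]]])


def test_max_pool_drops_trailing_partial_window():
    x = Tensor(np.arange(7.0).reshape(1, 1, 7))
    assert x.max_pool1d(3).data.shape == (1, 1, 2)


# ------------------------------------------------------------------ softmax
def test_softmax_of_zero_vector_is_uniform():
    out = Tensor(np.zeros(5)).softmax().data
    np.testing.assert_allclose(out, np.full(5, 0.2))


def test_softmax_shift_invariance_and_direct_formula(rng):
    x = np.array([1.0, 2.0, 3.0])
    out = Tensor(x).softmax().data
    expect = np.exp(x) / np.exp(x).sum()
    np.testing.assert_allclose(out, expect, atol=1e-12)
    shifted = Tensor(x + 123.4).softmax().data
    np.testing.assert_allclose(out, shifted, atol=1e-12)


# ----------------------------------------------------------------- attention
def test_zero_query_weights_give_uniform_attention(rng):
    x = Tensor(rng.standard_normal((4, 3)))
    attn, _ = attention_head(x, Tensor(np.zeros((3, 2))),
                             Tensor(rng.standard_normal((3, 2))),
                             Tensor(rng.standard_normal((3, 2))))
    np.testing.assert_allclose(attn.data, np.full((4, 4), 0.25), atol=1e-12)


def test_attention_head_matches_scalar_oracle():
    """d=2, d_k=1: every matrix entry reproduced with plain float arithmetic."""
    x = np.array([[1.0, 2.0], [3.0, -1.0]])             # (d=2, f=2)
    wq = np.array([[0.5], [-0.2]])
    wk = np.array([[0.1], [0.3]])
    wv = np.array([[1.0], [2.0]])
    q = [x[0] @ wq[:, 0], x[1] @ wq[:, 0]]
    k = [x[0] @ wk[:, 0], x[1] @ wk[:, 0]]
    v = [x[0] @ wv[:, 0], x[1] @ wv[:, 0]]
    # scores scaled by 1/sqrt(d_k) with d_k = 1
    a_oracle = np.zeros((2, 2))
    for i in range(2):
        row = [math.exp(q[i] * k[j] / math.sqrt(1)) for j in range(2)]
        a_oracle[i] = np.array(row) / sum(row)
    z_oracle = a_oracle @ np.array(v)[:, None]
    attn, z = attention_head(Tensor(x), Tensor(wq), Tensor(wk), Tensor(wv))
    np.testing.assert_allclose(attn.data, a_oracle, atol=1e-9)
    np.testing.assert_allclose(z.data, z_oracle, atol=1e-9)


def test_attention_scores_are_scaled_by_sqrt_dk(rng):
    """Same Q/K at d_k=4: halving the scale vs the unscaled softmax."""
    x = Tensor(rng.standard_normal((3, 5)))
    wq, wk = rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
    wv = rng.standard_normal((5, 4))
    attn, _ = attention_head(x, Tensor(wq), Tensor(wk), Tensor(wv))
    scores = (x.data @ wq) @ (x.data @ wk).T / np.sqrt(4)
    expect = np.exp(scores - scores.max(1, keepdims=True))
    expect /= expect.sum(1, keepdims=True)
    np.testing.assert_allclose(attn.data, expect, atol=1e-12)


def test_attention_rows_sum_to_one(rng, tiny_model):
    x = random_onehot(rng, 3, tiny_model.config.seq_len)
    res = tiny_model.forward(x)
    np.testing.assert_allclose(res.attention.sum(axis=-1), 1.0, atol=1e-6)
    assert res.attention.min() >= 0.0 and res.attention.max() <= 1.0


# ------------------------------------------------------------- combine heads
def test_combine_output_is_standardized(rng):
    heads = [Tensor(rng.standard_normal((2, 6, 4))) for _ in range(3)]
    out = combine_heads(heads, Tensor(rng.standard_normal((12, 5))))
    np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-6)
    np.testing.assert_allclose(out.data.std(axis=-1), 1.0, atol=1e-6)


def test_combine_single_head_identity_map_matches_oracle(rng):
    z = rng.standard_normal((1, 4, 3))
    out = combine_heads([Tensor(z)], Tensor(np.eye(3)))
    summed = z[0].sum(axis=0)                        # addition over positions
    expect = (summed - summed.mean()) / summed.std()
    np.testing.assert_allclose(out.data[0], expect, atol=1e-6)


def test_combine_constant_vector_yields_zeros():
    z = Tensor(np.ones((1, 4, 2)))
    out = combine_heads([z], Tensor(np.ones((2, 3))))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-3)


def test_combine_requires_heads():
    with pytest.raises(ValueError):
        combine_heads([], Tensor(np.eye(2)))


# ---------------------------------------------------------------------- LSTM
def lstm_params(rng, f, h):
    return {"w": Tensor(rng.standard_normal((f, 4 * h)) * 0.1, requires_grad=True),
            "u": Tensor(rng.standard_normal((h, 4 * h)) * 0.1, requires_grad=True),
            "b": Tensor(np.zeros(4 * h), requires_grad=True)}


@pytest.mark.parametrize("t_steps", [1, 4, 7])
def test_lstm_output_length_matches_input(rng, t_steps):
    params = lstm_params(rng, 3, 5)
    out = lstm_layer(Tensor(rng.standard_normal((2, t_steps, 3))), params)
    assert out.shape == (2, t_steps, 5)


def test_lstm_zero_weights_zero_input_gives_zero_output():
    """Hand-rolled recurrence: all-zero gates -> i=f=o=1/2, g=0, c=0, h=0."""
    params = {"w": Tensor(np.zeros((2, 8))), "u": Tensor(np.zeros((2, 8))),
              "b": Tensor(np.zeros(8))}
    out = lstm_layer(Tensor(np.zeros((1, 3, 2))), params)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_lstm_is_deterministic(rng):
    params = lstm_params(rng, 3, 4)
    x = Tensor(rng.standard_normal((2, 5, 3)))
    a = lstm_layer(x, params).data
    b = lstm_layer(x, params).data
    np.testing.assert_array_equal(a, b)


def test_bidirectional_model_doubles_feature_width(rng):
    cfg = ModelConfig(seq_len=36, n_filters=4, filter_len=5, pool_window=2,
                      n_heads=2, d_k=3, attn_out=3, use_rnn=True, rnn_hidden=6)
    model = Model(cfg, seed=0)
    res = model.forward(random_onehot(rng, 2, 36))
    assert res.logits.shape == (2, 2)
    assert cfg.attn_in_features == 12


# -------------------------------------------------------------------- losses
def test_binary_loss_matches_log2_oracle():
    logits = Tensor(np.array([[0.0, 0.0]]))
    assert loss_binary(logits, np.array([1])).item() == pytest.approx(np.log(2))


def test_multilabel_loss_matches_direct_formula():
    # C=2, y=(1,0), yhat=(0,0): loss = -(1/2)[log .5 + log .5] = log 2
    logits = Tensor(np.zeros((1, 2)))
    got = loss_multilabel(logits, np.array([[1, 0]])).item()
    assert got == pytest.approx(np.log(2), abs=1e-12)


def test_loss_limits_and_nonnegativity(rng):
    confident = Tensor(np.array([[30.0]]))
    assert loss_multilabel(confident, np.array([[1]])).item() < 1e-12
    logits = Tensor(rng.standard_normal((5, 3)))
    labels = (rng.random((5, 3)) < 0.5).astype(float)
    assert loss_multilabel(logits, labels).item() >= 0.0


def test_loss_shape_mismatch_raises():
    with pytest.raises(ValueError):
        loss_binary(Tensor(np.zeros((2, 3))), np.array([0, 1]))
    with pytest.raises(ValueError):
        loss_multilabel(Tensor(np.zeros((2, 3))), np.zeros((2, 2)))


# ------------------------------------------------------------------- forward
def test_forward_shapes_binary_and_multilabel(rng):
    x = random_onehot(rng, 3, 40)
    binary = Model(ModelConfig(seq_len=40, n_filters=3, filter_len=5,
                               pool_window=3, n_heads=2, d_k=4, attn_out=4),
                   seed=0)
    assert binary.forward(x).logits.shape == (3, 2)
    multi = Model(ModelConfig(seq_len=40, n_filters=3, filter_len=5,
                              pool_window=3, n_heads=2, d_k=4, attn_out=4,
                              task="multilabel", n_tasks=6), seed=0)
    assert multi.forward(x).logits.shape == (3, 6)


def test_attention_matrix_dimension_is_floor_lprime_over_pool(rng, tiny_model):
    cfg = tiny_model.config
    d = (cfg.seq_len - cfg.filter_len + 1) // cfg.pool_window
    res = tiny_model.forward(random_onehot(rng, 1, cfg.seq_len))
    assert res.attention.shape == (1, cfg.n_heads, d, d)
    assert cfg.d == d


def test_pool_window_one_keeps_conv_resolution(rng):
    cfg = ModelConfig(seq_len=30, n_filters=2, filter_len=4, pool_window=1,
                      n_heads=1, d_k=3, attn_out=3)
    res = Model(cfg, seed=1).forward(random_onehot(rng, 1, 30))
    assert res.pooled.shape == (1, 2, 27)
    np.testing.assert_array_equal(res.pooled, res.conv_map)


def test_full_model_gradient_check(rng):
    """Analytic gradients of forward+loss vs central differences (d=4, F=3)."""
    cfg = ModelConfig(seq_len=17, n_filters=3, filter_len=2, pool_window=4,
                      n_heads=2, d_k=3, attn_out=3)
    model = Model(cfg, seed=2)
    assert cfg.d == 4
    x = random_onehot(rng, 2, 17)
    y = np.array([0, 1])

    def f():
        return model.loss(model.forward(x), y).item()

    model.zero_grad()
    model.loss(model.forward(x), y).backward()
    eps = 1e-6
    for name, p in model.params.items():
        flat_idx = [tuple(rng.integers(0, s) for s in p.data.shape)
                    for _ in range(3)]
        for idx in flat_idx:
            old = p.data[idx]
            p.data[idx] = old + eps
            fp = f()
            p.data[idx] = old - eps
            fm = f()
            p.data[idx] = old
            num = (fp - fm) / (2 * eps)
            rel = abs(num - p.grad[idx]) / max(abs(num), abs(p.grad[idx]), 1e-8)
            assert rel < 1e-4, f"{name}[{idx}]: {num} vs {p.grad[idx]}"


def test_checkpoint_roundtrip(tmp_path, rng, tiny_model):
    x = random_onehot(rng, 2, tiny_model.config.seq_len)
    before = tiny_model.forward(x).logits.data
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = Model.load(path)
    np.testing.assert_array_equal(loaded.forward(x).logits.data, before)
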