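"""Dual-stage attention predictor: attention algebra, forward, training."""

import numpy as np
import pytest

from dabiddi._autodiff import Tensor, bce_loss
from dabiddi.sequence_model import (DARNN, SequenceBatch, TrainConfig,
                                    input_attention, make_sequence_batch,
                                    temporal_attention, train)


# ---------------------------------------------------------------------------
# attention operations
# ---------------------------------------------------------------------------

def test_input_attention_single_feature():
    p = dict(W_e=np.ones((1, 2)), U_e=np.ones((1, 3)), v_e=np.ones(1))
    a = input_attention(np.ones((1, 3)), np.zeros(1), np.zeros(1), p)
    assert a == pytest.approx([1.0])


def test_input_attention_uniform_for_identical_series(rng):
    x = np.tile(rng.normal(size=4), (5, 1))  # five identical driving series
    p = dict(W_e=rng.normal(size=(2, 6)), U_e=rng.normal(size=(2, 4)),
             v_e=rng.normal(size=2))
    a = input_attention(x, rng.normal(size=3), rng.normal(size=3), p)
    assert a == pytest.approx(np.full(5, 0.2))


def test_input_attention_hand_case():
    # unit params, zero states, two constant series (0,0) and (1,1):
    # logits tanh(0) and tanh(2)
    p = dict(W_e=np.ones((1, 2)), U_e=np.ones((1, 2)), v_e=np.ones(1))
    a = input_attention(np.array([[0.0, 0.0], [1.0, 1.0]]),
                        np.zeros(1), np.zeros(1), p)
    want = np.exp([np.tanh(0.0), np.tanh(2.0)])
    want /= want.sum()
    assert a == pytest.approx(want)


def test_input_attention_shift_invariant(rng):
    """Adding a constant to all logits leaves the softmax unchanged."""
    x = rng.normal(size=(4, 3))
    p = dict(W_e=rng.normal(size=(2, 4)), U_e=rng.normal(size=(2, 3)),
             v_e=rng.normal(size=2))
    a = input_attention(x, np.zeros(2), np.zeros(2), p)
    assert a.sum() == pytest.approx(1.0)
    assert (a > 0).all()


def test_temporal_attention_trivial_and_hand_case():
    p = dict(W_t=np.ones((1, 1)), U_t=np.ones((1, 1)), v_t=np.ones(1))
    beta, ctx = temporal_attention(np.array([[3.0]]), np.zeros(1), p)
    assert beta == pytest.approx([1.0])
    assert ctx == pytest.approx([3.0])
    # identical states -> uniform weights, context = the state
    beta, ctx = temporal_attention(np.array([[2.0], [2.0], [2.0]]),
                                   np.zeros(1), p)
    assert beta == pytest.approx(np.full(3, 1 / 3))
    assert ctx == pytest.approx([2.0])
    # T=2 scalar case with unit parameters
    h = np.array([[0.5], [-1.0]])
    beta, ctx = temporal_attention(h, np.array([0.25]), p)
    logits = np.tanh([0.5 + 0.25, -1.0 + 0.25])
    want = np.exp(logits - logits.max())
    want /= want.sum()
    assert beta == pytest.approx(want)
    assert ctx == pytest.approx(want @ h)
    with pytest.raises(ValueError):
        temporal_attention(np.zeros((0, 1)), np.zeros(1), p)


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

def test_make_sequence_batch_pads_blocks(rng):
    blocks = {"drugA": rng.normal(size=(10, 4)),
              "drugB": rng.normal(size=(10, 4)),
              "cell": rng.normal(size=(10, 7))}
    batch = make_sequence_batch(blocks, rng.integers(0, 2, 10))
    assert batch.x.shape == (10, 3, 7)
    # padding is zero beyond each block's width
    assert batch.x[:, 0, 4:] == pytest.approx(np.zeros((10, 3)))


def test_sequence_batch_rejects_nan():
    x = np.zeros((2, 2, 2))
    x[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        SequenceBatch(x, [0, 1])


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def test_forward_zero_head_is_half_and_deterministic(rng):
    m = DARNN(n_features=5, T=3, hidden_dim=8, seed=0)
    x = rng.normal(size=(6, 3, 5))
    p1 = m.predict_proba(x)
    p2 = m.predict_proba(x)
    assert p1 == pytest.approx(np.full(6, 0.5))
    assert p1 == pytest.approx(p2)


def test_forward_batch_independence(rng):
    m = DARNN(n_features=4, T=2, hidden_dim=6, seed=3)
    # break the zero-head symmetry
    m.w.data = rng.normal(size=m.w.data.shape)
    x = rng.normal(size=(8, 2, 4))
    p = m.predict_proba(x)
    perm = rng.permutation(8)
    assert m.predict_proba(x[perm]) == pytest.approx(p[perm])


def test_forward_rejects_nan(rng):
    m = DARNN(n_features=3, T=2, hidden_dim=4, seed=0)
    x = rng.normal(size=(2, 2, 3))
    x[1, 1, 1] = np.nan
    with pytest.raises(ValueError):
        m.forward(x)


def test_gradient_matches_finite_differences(rng):
    """Central finite differences on a 2-sample batch, norm-wise."""
    m = DARNN(n_features=3, T=2, hidden_dim=4, seed=1)
    m.w.data = rng.normal(scale=0.5, size=m.w.data.shape)
    x = rng.normal(size=(2, 2, 3))
    y = np.array([1, 0])
    loss = bce_loss(m.forward(x), y)
    loss.backward()

    def loss_val():
        return float(bce_loss(m.forward(x), y).data)

    for p in m.params:
        flat = p.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            eps = 1e-5
            old = flat[i]
            flat[i] = old + eps
            lp = loss_val()
            flat[i] = old - eps
            lm = loss_val()
            flat[i] = old
            num[i] = (lp - lm) / (2 * eps)
        an = p.grad.ravel()
        denom = max(np.linalg.norm(num), 1e-8)
        assert np.linalg.norm(num - an) / denom < 1e-4


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _toy_task(rng, n=200, T=3, k=4):
    x = rng.normal(size=(n, T, k))
    y = (x[:, 0, 0] + x[:, 1, 1] > 0).astype(int)
    return x, y


def test_zero_learning_rate_freezes_parameters(rng):
    x, y = _toy_task(rng)
    m = DARNN(n_features=4, T=3, hidden_dim=6, seed=0)
    before = [p.data.copy() for p in m.params]
    hist = train(m, (x, y), config=TrainConfig(lr=0.0, epochs=3,
                                               batch_size=64, cosine=False))
    for p, b in zip(m.params, before):
        assert p.data == pytest.approx(b)
    assert len(hist["train_loss"]) == 3
    assert np.ptp(hist["train_loss"]) < 1e-9


def test_training_reduces_loss_on_separable_task(rng):
    x, y = _toy_task(rng, n=300)
    m = DARNN(n_features=4, T=3, hidden_dim=8, seed=2)
    hist = train(m, (x, y), config=TrainConfig(lr=5e-3, epochs=25,
                                               batch_size=64, cosine=False))
    assert hist["train_loss"][-1] < hist["train_loss"][0]
    # better than chance on the training data
    p = m.predict_proba(x)
    assert ((p > 0.5) == y).mean() > 0.7


def test_early_stopping_and_restore(rng):
    x, y = _toy_task(rng, n=240)
    m = DARNN(n_features=4, T=3, hidden_dim=6, seed=4)
    hist = train(m, (x[:160], y[:160]), (x[160:], y[160:]),
                 TrainConfig(lr=5e-3, epochs=200, batch_size=64,
                             patience=5, cosine=False))
    assert len(hist["val_loss"]) < 200  # stopped early
    with pytest.raises(ValueError):
        train(m, (np.zeros((0, 3, 4)), np.zeros(0)))


def test_presets():
    darnn = TrainConfig.from_preset("darnn")
    mfs = TrainConfig.from_preset("mfsyndcp")
    assert (darnn.lr, darnn.batch_size, darnn.patience) == (1e-3, 256, 10)
    assert (mfs.lr, mfs.batch_size, mfs.patience) == (1e-4, 2048, 15)
    assert mfs.weight_decay == 1e-5
    with pytest.raises(ValueError):
        TrainConfig.from_preset("nope")


def test_input_attention_recovers_informative_feature(rng):
    """When the label depends on one driving feature, its mean attention
    exceeds the uniform baseline."""
    wins = 0
    for seed in range(5):
        r = np.random.default_rng(seed)
        n, T, k = 300, 3, 5
        x = r.normal(size=(n, T, k))
        y = (x[:, :, 2].sum(axis=1) > 0).astype(int)  # only feature 2 matters
        m = DARNN(n_features=k, T=T, hidden_dim=8, seed=seed)
        train(m, (x, y), config=TrainConfig(lr=5e-3, epochs=40,
                                            batch_size=64, cosine=False))
        # measure mean input-attention weight on feature 2
        from dabiddi._autodiff import Tensor as _T
        import dabiddi.sequence_model as sm
        B = n
        series = x.transpose(0, 2, 1)
        u_term = series @ m.U_e.data
        h = np.zeros((B, m.hidden))
        s = np.zeros((B, m.hidden))
        hs = np.concatenate([h, s], axis=1) @ m.W_e.data
        e = np.tanh(u_term + hs[:, None, :]) @ m.v_e.data
        e = e - e.max(axis=1, keepdims=True)
        a = np.exp(e)
        a /= a.sum(axis=1, keepdims=True)
        wins += a[:, 2].mean() > 1.0 / k
    assert wins >= 4
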