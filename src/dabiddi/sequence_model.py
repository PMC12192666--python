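"""Dual-stage attention recurrent predictor over fused feature sequences.

The fused multi-source feature vector of a (drugA, drugB, cell) triplet is
partitioned into T ordered blocks (drugA | drugB | GGI | CTF | cell |
Bayesian evidence), each block one pseudo-time step of width n (padded to
the widest block).  The
encoder applies *input attention* — a softmax over the n driving features,
scored from the previous encoder hidden/cell states and each feature's full
driving series — followed by an LSTM step on the attention-weighted input.
The decoder applies *temporal attention* over the encoder states and an
LSTM on the resulting context; a sigmoid head maps the final decoder state
and context to an interaction probability.

Input attention:   e_t^k = v_e . tanh(W_e [h_{t-1}; s_{t-1}] + U_e x^k)
                   alpha_t = softmax_k(e_t)
Temporal attention: l_t^i = v_t . tanh(W_t h_i + U_t d_t)
                   beta_t = softmax_i(l_t),  c_t = sum_i beta_t^i h_i

Training uses Adam with binary cross-entropy and early stopping on
validation loss.  Two named presets ship: ``darnn`` (default; lr 1e-3 with
cosine annealing, batch 256, patience 10) and ``mfsyndcp`` (lr 1e-4, weight
decay 1e-5, batch 2048, patience 15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, bce_loss, concat, softmax, stack

__all__ = [
    "SequenceBatch", "make_sequence_batch", "DARNN", "TrainConfig",
    "input_attention", "temporal_attention", "train",
]

BLOCK_ORDER = ("drugA", "drugB", "ggi", "ctf", "cell", "bayes")


@dataclass
class SequenceBatch:
    """x: (batch, T, n) driving series; labels: binary (batch,)."""

    x: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.x.ndim != 3:
            raise ValueError("x must be (batch, T, n)")
        if len(self.labels) != self.x.shape[0]:
            raise ValueError("labels length must match batch size")
        if not np.isfinite(self.x).all():
            raise ValueError("non-finite values in sequence batch")

    @property
    def T(self):
        return self.x.shape[1]

    @property
    def n(self):
        return self.x.shape[2]


def make_sequence_batch(blocks: dict, labels, order=BLOCK_ORDER,
                        normalize: bool = True) -> SequenceBatch:
    """Assemble per-sample feature blocks into a padded (B, T, n) batch.

    ``blocks`` maps block name -> (B, width) array; missing blocks are
    skipped, present ones are z-scored per feature (population statistics)
    and zero-padded to the widest block.
    """
    mats = []
    for name in order:
        if name not in blocks or blocks[name] is None:
            continue
        m = np.atleast_2d(np.asarray(blocks[name], dtype=float))
        if normalize:
            mu = m.mean(axis=0)
            sd = m.std(axis=0)
            sd[sd < 1e-12] = 1.0
            m = (m - mu) / sd
        mats.append(m)
    if not mats:
        raise ValueError("no feature blocks provided")
    n = max(m.shape[1] for m in mats)
    padded = [np.pad(m, ((0, 0), (0, n - m.shape[1]))) for m in mats]
    return SequenceBatch(np.stack(padded, axis=1), labels)


# ---------------------------------------------------------------------------
# standalone attention operations (numpy; unit-testable in isolation)
# ---------------------------------------------------------------------------

def input_attention(x_series: np.ndarray, h_prev: np.ndarray,
                    s_prev: np.ndarray, params: dict) -> np.ndarray:
    """Input-attention weights over the n driving features at one step.

    ``x_series`` is (n, T): row k is the full driving series of feature k
    (the U_e term reads the whole series, as in the dual-stage formulation).
    Returns alpha (n,), positive, summing to one.
    """
    x_series = np.atleast_2d(np.asarray(x_series, dtype=float))
    n = x_series.shape[0]
    if n == 0:
        raise ValueError("need at least one driving feature")
    W_e, U_e, v_e = (np.atleast_2d(params["W_e"]),
                     np.atleast_2d(params["U_e"]),
                     np.atleast_1d(params["v_e"]))
    hs = np.concatenate([np.atleast_1d(h_prev), np.atleast_1d(s_prev)])
    e = np.tanh(W_e @ hs + (U_e @ x_series.T).T) @ v_e  # (n,)
    e = e - e.max()
    a = np.exp(e)
    return a / a.sum()


def temporal_attention(h_states: np.ndarray, d_t: np.ndarray,
                       params: dict):
    """Temporal-attention weights over encoder states and the context.

    ``h_states`` is (T, h).  Returns (beta, context) with beta summing to
    one and context = sum_i beta_i h_i.
    """
    h_states = np.atleast_2d(np.asarray(h_states, dtype=float))
    if h_states.shape[0] == 0:
        raise ValueError("need at least one encoder state")
    W_t, U_t, v_t = (np.atleast_2d(params["W_t"]),
                     np.atleast_2d(params["U_t"]),
                     np.atleast_1d(params["v_t"]))
    l = np.tanh(h_states @ W_t.T + U_t @ np.atleast_1d(d_t)) @ v_t
    l = l - l.max()
    b = np.exp(l)
    beta = b / b.sum()
    return beta, beta @ h_states


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _lstm_step(x, h, s, Wx, Wh, b, hdim):
    """One LSTM cell update on a batch; returns (h', s')."""
    z = x @ Wx + h @ Wh + b
    i = z[:, 0 * hdim:1 * hdim].sigmoid()
    f = z[:, 1 * hdim:2 * hdim].sigmoid()
    o = z[:, 2 * hdim:3 * hdim].sigmoid()
    g = z[:, 3 * hdim:4 * hdim].tanh()
    s_new = f * s + i * g
    h_new = o * s_new.tanh()
    return h_new, s_new


class DARNN:
    """Dual-stage attention recurrent network for binary interaction labels.

    ``use_lstm=False`` removes the recurrent capacity entirely (the
    neutral identity stand-in used by the ablation harness): encoder
    states are the attention-weighted inputs and the decoder state is the
    attention context passed through unchanged, leaving both attention
    stages and the linear head in place.
    """

    def __init__(self, n_features: int, T: int, hidden_dim: int = 256,
                 att_dim: int = 16, dropout: float = 0.3, seed: int = 0,
                 use_lstm: bool = True):
        rng = np.random.default_rng(seed)
        self.n, self.T = n_features, T
        self.hidden = hidden_dim if use_lstm else n_features
        self.dec = max(hidden_dim // 2, 4) if use_lstm else self.hidden
        self.dropout = dropout
        self.use_lstm = use_lstm
        h, p, m, n = self.hidden, self.dec, att_dim, n_features

        def W(*shape, scale=None):
            scale = scale or 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(scale=scale, size=shape), requires_grad=True)

        # input attention
        self.W_e = W(2 * h, m)
        self.U_e = W(T, m)
        self.v_e = W(m)
        # encoder LSTM (forget-gate bias starts at 1: standard init that
        # keeps early gradients flowing through the cell state)
        if use_lstm:
            self.Wx = W(n, 4 * h)
            self.Wh = W(h, 4 * h)
            be = np.zeros(4 * h)
            be[h:2 * h] = 1.0
            self.be = Tensor(be, requires_grad=True)
        # temporal attention
        self.W_t = W(h, m)
        self.U_t = W(p, m)
        self.v_t = W(m)
        # decoder LSTM (input = context vector)
        if use_lstm:
            self.Wc = W(h, 4 * p)
            self.Wd = W(p, 4 * p)
            bd = np.zeros(4 * p)
            bd[p:2 * p] = 1.0
            self.bd = Tensor(bd, requires_grad=True)
        # prediction head (zero init: untrained output is exactly 0.5)
        self.w = Tensor(np.zeros(p + h), requires_grad=True)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self):
        ps = [self.W_e, self.U_e, self.v_e, self.W_t, self.U_t, self.v_t,
              self.w, self.b]
        if self.use_lstm:
            ps += [self.Wx, self.Wh, self.be, self.Wc, self.Wd, self.bd]
        return ps

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator = None) -> Tensor:
        """Interaction probabilities for a (B, T, n) batch as a Tensor."""
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("NaN or Inf in model input")
        B, T, n = x.shape
        if T != self.T or n != self.n:
            raise ValueError("batch shape does not match model (T, n)")
        h = Tensor(np.zeros((B, self.hidden)))
        s = Tensor(np.zeros((B, self.hidden)))
        series = Tensor(np.transpose(x, (0, 2, 1)))  # (B, n, T)
        u_term = series @ self.U_e                   # (B, n, m)
        states = []
        for t in range(T):
            hs = concat([h, s], axis=1) @ self.W_e       # (B, m)
            e = ((u_term + hs.reshape(B, 1, -1)).tanh() @ self.v_e)  # (B, n)
            alpha = softmax(e, axis=1)
            xt = alpha * Tensor(x[:, t, :])
            if self.use_lstm:
                h, s = _lstm_step(xt, h, s, self.Wx, self.Wh, self.be,
                                  self.hidden)
            else:
                h = xt
            states.append(h)
        H = stack(states, axis=1)                    # (B, T, h)
        if train and self.dropout > 0:
            rng = rng or np.random.default_rng()
            mask = (rng.random(H.shape) >= self.dropout) / (1 - self.dropout)
            H = H * Tensor(mask)
        d = Tensor(np.zeros((B, self.dec)))
        sd = Tensor(np.zeros((B, self.dec)))
        ctx = None
        for _ in range(T):
            l = ((H @ self.W_t + (d @ self.U_t).reshape(B, 1, -1)).tanh()
                 @ self.v_t)                         # (B, T)
            beta = softmax(l, axis=1)
            ctx = (beta.reshape(B, T, 1) * H).sum(axis=1)   # (B, h)
            if self.use_lstm:
                d, sd = _lstm_step(ctx, d, sd, self.Wc, self.Wd, self.bd,
                                   self.dec)
            else:
                d = ctx  # identity pass-through of the context
        logit = concat([d, ctx], axis=1) @ self.w + self.b[0]
        return logit.sigmoid()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode probabilities (dropout disabled)."""
        return self.forward(x, train=False).data.copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    patience: int = 10
    hidden_dim: int = 256
    dropout: float = 0.3
    weight_decay: float = 0.0
    cosine: bool = True
    seed: int = 0
    preset: str = "darnn"

    @classmethod
    def from_preset(cls, preset: str = "darnn", **overrides) -> "TrainConfig":
        base = {
            "darnn": dict(lr=1e-3, batch_size=256, patience=10, cosine=True,
                          weight_decay=0.0),
            "mfsyndcp": dict(lr=1e-4, batch_size=2048, patience=15,
                             cosine=False, weight_decay=1e-5, epochs=200),
        }
        if preset not in base:
            raise ValueError(f"unknown preset: {preset!r}")
        kw = dict(base[preset], preset=preset)
        kw.update(overrides)
        return cls(**kw)


def train(model: DARNN, train_data, val_data=None,
          config: TrainConfig = TrainConfig()):
    """Fit with Adam + early stopping on validation loss.

    ``train_data``/``val_data`` are (x, labels) arrays or SequenceBatch.
    Returns a history dict with per-epoch train (and val) losses; the model
    is restored to the best-validation parameters.
    """
    def unpack(data):
        if isinstance(data, SequenceBatch):
            return data.x, data.labels
        return np.asarray(data[0], dtype=float), np.asarray(data[1])

    x_tr, y_tr = unpack(train_data)
    if len(y_tr) == 0:
        raise ValueError("empty training set")
    has_val = val_data is not None
    if has_val:
        x_va, y_va = unpack(val_data)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, since_best = np.inf, None, 0

    for epoch in range(config.epochs):
        if config.cosine:
            opt.lr = config.lr * 0.5 * (1 + np.cos(np.pi * epoch / config.epochs))
        order = rng.permutation(len(y_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            p = model.forward(x_tr[idx], train=True, rng=rng)
            loss = bce_loss(p, y_tr[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if has_val:
            pv = model.predict_proba(x_va)
            vl = float(bce_loss(Tensor(pv), y_va).data)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val, since_best = vl, 0
                best_state = [p.data.copy() for p in model.params]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        for p, d in zip(model.params, best_state):
            p.data = d
    return history
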