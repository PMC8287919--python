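"""Convolution + multi-head self-attention sequence model.

Architecture (one forward pass)::

    one-hot (4 x L)
      -> valid 1-D convolution, F filters of length A   (F x L')
      -> ReLU
      -> non-overlapping max-pool, window M_p           (F x d), d = floor(L'/M_p)
      -> optional bidirectional LSTM over the d positions
      -> k self-attention heads: A_h = softmax(Q K^T / sqrt(d_k)), Z_h = A_h V
      -> concatenate heads, linear map, collapse by addition over the d
         positions, standardize the resulting feature vector to mean 0 / sd 1
      -> fully connected readout (2 logits for binary, C for multi-label)

The pooling window is kept small (~6 bp) so each attended position still
corresponds to a narrow genomic window; that is what later lets attention
entries be assigned to individual convolutional filters.

Every intermediate a downstream interpretation step needs — the per-head
attention matrices, the ReLU convolution map and the pooled map — is
returned by :meth:`Model.forward` so interaction scoring never re-runs
the network.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "ModelConfig", "Model", "ForwardResult",
    "attention_head", "combine_heads", "lstm_layer",
    "loss_binary", "loss_multilabel",
]


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the promoter-scale configuration.

    ``task`` is ``"binary"`` (2-logit cross entropy; the reported
    probability is the softmax weight of the positive class) or
    ``"multilabel"`` with ``n_tasks`` sigmoid outputs.
    """

    seq_len: int = 300
    n_filters: int = 200
    filter_len: int = 13
    pool_window: int = 6
    n_heads: int = 8
    d_k: int = 64
    attn_out: int = 64          # feature size after the post-concat linear map
    use_rnn: bool = False
    rnn_hidden: int = 32
    task: str = "binary"
    n_tasks: int = 1
    std_eps: float = 1e-8       # guards standardization of constant vectors

    def __post_init__(self):
        if self.pool_window < 1 or self.n_heads < 1 or self.d_k < 1:
            raise ValueError("pool_window, n_heads and d_k must all be >= 1")
        if self.task not in ("binary", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def conv_out_len(self) -> int:
        return self.seq_len - self.filter_len + 1

    @property
    def d(self) -> int:
        """Attended sequence length: floor(L' / M_p)."""
        return self.conv_out_len // self.pool_window

    @property
    def attn_in_features(self) -> int:
        return 2 * self.rnn_hidden if self.use_rnn else self.n_filters

    @property
    def n_logits(self) -> int:
        return 2 if self.task == "binary" else self.n_tasks


@dataclasses.dataclass
class ForwardResult:
    """Everything one forward pass produces.

    ``logits`` stays a :class:`Tensor` (differentiable); the
    interpretation artifacts are plain arrays.
    """

    logits: Tensor
    attention: np.ndarray      # (N, k, d, d) row-stochastic per head
    conv_map: np.ndarray       # (N, F, L') post-ReLU filter activations
    pooled: np.ndarray         # (N, F, d) max-pooled activations

    def probabilities(self, task: str) -> np.ndarray:
        z = self.logits.data
        if task == "binary":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return (e / e.sum(axis=1, keepdims=True))[:, 1]
        return 1.0 / (1.0 + np.exp(-z))


def attention_head(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor
                   ) -> tuple[Tensor, Tensor]:
    """One self-attention head.

    ``x`` is (..., d, f); the projections give Q, K, V of shape
    (..., d, d_k).  Returns the row-stochastic attention matrix
    ``A = softmax(Q K^T / sqrt(d_k))`` and the head output ``Z = A V``.
    """
    q = x @ w_q
    k = x @ w_k
    v = x @ w_v
    d_k = w_k.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    attn = scores.softmax(axis=-1)
    return attn, attn @ v


def combine_heads(heads: list[Tensor], w_o: Tensor, eps: float = 1e-8) -> Tensor:
    """Concatenate head outputs, map linearly, collapse and standardize.

    The concatenated (..., d, k*d_k) tensor is passed through ``w_o``,
    collapsed by addition over the attended positions to one value per
    feature, and the resulting feature vector standardized to mean 0 /
    sd 1 per example.  Collapsing over positions (rather than features)
    makes the readout invariant to where in the sequence a motif sits —
    a motif planted at a random position is otherwise invisible to a
    linear readout of a standardized positional profile.  ``eps`` is
    added to the standard deviation so constant vectors map to zeros
    instead of NaN.
    """
    if not heads:
        raise ValueError("combine_heads requires at least one head")
    cat = heads[0] if len(heads) == 1 else concatenate(heads, axis=-1)
    mapped = cat @ w_o
    collapsed = mapped.sum(axis=-2)                     # (..., attn_out)
    mu = collapsed.mean(axis=-1, keepdims=True)
    centered = collapsed - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    sd = (var + eps * eps) ** 0.5
    return centered / (sd + eps)


def lstm_layer(x: Tensor, params: dict[str, Tensor], reverse: bool = False) -> Tensor:
    """Single-direction LSTM over axis -2 of ``x`` (shape (N, T, f)).

    ``params`` holds ``w`` (f, 4H), ``u`` (H, 4H) and ``b`` (4H,) with
    gate order [input, forget, cell, output].  Returns (N, T, H).
    """
    n, t_steps, _ = x.shape
    hidden = params["u"].shape[0]
    h = Tensor(np.zeros((n, hidden)))
    c = Tensor(np.zeros((n, hidden)))
    outs: list[Tensor] = []
    order = range(t_steps - 1, -1, -1) if reverse else range(t_steps)
    for t in order:
        xt = x[:, t, :]
        gates = xt @ params["w"] + h @ params["u"] + params["b"]
        i = gates[:, :hidden].sigmoid()
        f = gates[:, hidden:2 * hidden].sigmoid()
        g = gates[:, 2 * hidden:3 * hidden].tanh()
        o = gates[:, 3 * hidden:].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outs.append(h)
    if reverse:
        outs.reverse()
    from .autodiff import stack
    return stack(outs, axis=1)


def loss_binary(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Standard cross entropy over 2 logits (mean over the batch)."""
    labels = np.asarray(labels).astype(np.int64).ravel()
    if logits.shape[0] != labels.shape[0] or logits.shape[1] != 2:
        raise ValueError(f"expected ({labels.shape[0]}, 2) logits, got {logits.shape}")
    logp = logits.log_softmax(axis=1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def loss_multilabel(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Binary cross entropy with logits, averaged over the C tasks.

    Per example: -(1/C) sum_i [y_i log sigma(yhat_i) +
    (1 - y_i) log(1 - sigma(yhat_i))]; the batch mean is returned.
    Computed through softplus, so large logits cannot overflow.
    """
    y = np.asarray(labels, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if tuple(logits.shape) != y.shape:
        raise ValueError(f"logit shape {logits.shape} != label shape {y.shape}")
    # y*log sigma(x) + (1-y)*log(1-sigma(x)) = x*y - x*(x>0 term) - softplus(-|x|)...
    # use: -[max(x,0) - x*y + softplus(-|x|)] summed, the standard stable form
    x = logits
    loss_terms = x.relu() - x * Tensor(y) + (-(abs_tensor(x))).softplus()
    return loss_terms.mean()


def abs_tensor(x: Tensor) -> Tensor:
    sign = np.sign(x.data)
    return Tensor._from_op(np.abs(x.data), (x,), lambda g: (g * sign,))


class Model:
    """The trainable network.  Parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, Tensor] = {}

        def glorot(*shape):
            fan = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return Tensor(rng.uniform(-fan, fan, size=shape), requires_grad=True)

        p["conv_w"] = glorot(c.n_filters, 4, c.filter_len)
        if c.use_rnn:
            for direction in ("fwd", "bwd"):
                p[f"lstm_{direction}_w"] = glorot(c.n_filters, 4 * c.rnn_hidden)
                p[f"lstm_{direction}_u"] = glorot(c.rnn_hidden, 4 * c.rnn_hidden)
                p[f"lstm_{direction}_b"] = Tensor(
                    np.zeros(4 * c.rnn_hidden), requires_grad=True)
        f_in = c.attn_in_features
        for h in range(c.n_heads):
            p[f"w_q_{h}"] = glorot(f_in, c.d_k)
            p[f"w_k_{h}"] = glorot(f_in, c.d_k)
            p[f"w_v_{h}"] = glorot(f_in, c.d_k)
        p["w_o"] = glorot(c.n_heads * c.d_k, c.attn_out)
        p["readout_w"] = glorot(c.attn_out, c.n_logits)
        p["readout_b"] = Tensor(np.zeros(c.n_logits), requires_grad=True)
        self.params = p

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray | Tensor) -> ForwardResult:
        """Run a batch (N, 4, L) through the network."""
        c = self.config
        xt = x if isinstance(x, Tensor) else Tensor(x)
        if xt.shape[1] != 4 or xt.shape[2] != c.seq_len:
            raise ValueError(
                f"expected input (N, 4, {c.seq_len}), got {tuple(xt.shape)}")
        conv = xt.conv1d(self.params["conv_w"]).relu()      # (N, F, L')
        pooled = conv.max_pool1d(c.pool_window)             # (N, F, d)
        feats = pooled.swapaxes(1, 2)                       # (N, d, F)
        if c.use_rnn:
            fwd = lstm_layer(feats, {k.split("_", 2)[2]: v for k, v in
                                     self.params.items() if k.startswith("lstm_fwd")})
            bwd = lstm_layer(feats, {k.split("_", 2)[2]: v for k, v in
                                     self.params.items() if k.startswith("lstm_bwd")},
                             reverse=True)
            feats = concatenate([fwd, bwd], axis=-1)        # (N, d, 2H)
        # standardize features per position before the Q/K/V projections:
        # conv activations grow unboundedly during training and would
        # otherwise saturate the softmax (vanishing attention gradients)
        mu = feats.mean(axis=-1, keepdims=True)
        centered = feats - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        feats = centered / ((var + c.std_eps ** 2) ** 0.5 + c.std_eps)
        attn_mats, head_outs = [], []
        for h in range(c.n_heads):
            a, z = attention_head(feats, self.params[f"w_q_{h}"],
                                  self.params[f"w_k_{h}"], self.params[f"w_v_{h}"])
            attn_mats.append(a.data)
            head_outs.append(z)
        combined = combine_heads(head_outs, self.params["w_o"], c.std_eps)  # (N, attn_out)
        logits = combined @ self.params["readout_w"] + self.params["readout_b"]
        return ForwardResult(logits=logits,
                             attention=np.stack(attn_mats, axis=1),
                             conv_map=conv.data, pooled=pooled.data)

    def loss(self, result: ForwardResult, labels: np.ndarray) -> Tensor:
        if self.config.task == "binary":
            return loss_binary(result.logits, labels)
        return loss_multilabel(result.logits, labels)

    # -------------------------------------------------------------- plumbing
    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def parameter_names(self) -> list[str]:
        return list(self.params)

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON + weight arrays."""
        path = Path(path)
        cfg = json.dumps(dataclasses.asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "Model":
        path = Path(path)
        if not path.exists() and path.suffix != ".npz":
            path = path.with_suffix(".npz")  # np.savez appends .npz on write
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = cls(ModelConfig(**cfg))
            for k in model.params:
                model.params[k] = Tensor(data[k], requires_grad=True)
        return model
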