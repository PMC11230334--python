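"""The encoder zoo: ten architectures mapping an embedded input to a fixed
vector.

Coarse (document-level) inputs are vectors and use the MLP family; fine
(token-level) inputs are ``L x D`` matrices and use the sequence families:
LSTM, GRU, their bidirectional variants, the four attention-pooled variants,
a 1-d CNN with mean-pooling, and the CNN-LSTM hybrid.

All encoders share the interface ``forward(x, mask) -> (B, F)`` where ``F``
is ``output_dim``: the hidden size H for unidirectional recurrences, 2H for
bidirectional ones, the projection dimension for the MLP and the filter
count for the CNN.  Variable-length batches are padded at the tail and
masked; masked positions never enter the recurrent state, the attention
softmax or the mean-pool.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import IO

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .exceptions import ConfigurationError, InputError
from .nn import BatchNorm1d, Dropout, Linear, Module, glorot

SEQUENCE_FAMILIES = (
    "lstm",
    "gru",
    "bilstm",
    "bigru",
    "lstm_att",
    "gru_att",
    "bilstm_att",
    "bigru_att",
    "cnn",
    "cnn_lstm",
)
VECTOR_FAMILIES = ("mlp",)
FAMILIES = VECTOR_FAMILIES + SEQUENCE_FAMILIES

#: dropout defaults: light for the MLP, heavy for sequence encoders
DEFAULT_DROPOUT = {"mlp": 0.1, "sequence": 0.5}


@dataclass
class EncoderConfig:
    """Declarative encoder description, YAML-serializable.

    hidden_units is the recurrent state size H (50 by default);
    projection_dim is the MLP output width (64 by default, the best value
    on the coarse grid {5, 10, 30, 50, 64, 100}).
    """

    family: str
    input_dim: int
    hidden_units: int = 50
    num_hidden_layers: int = 1
    projection_dim: int = 64
    dropout_rate: float | None = None
    cnn_filters: int = 64
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown encoder family {self.family!r}; choose from {FAMILIES}"
            )
        for name in ("input_dim", "hidden_units", "projection_dim", "cnn_filters",
                     "kernel_size", "num_hidden_layers"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.dropout_rate is not None and not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.family == "mlp" and not 1 <= self.num_hidden_layers <= 4:
            raise ConfigurationError("MLP supports 1-4 hidden layers")

    @property
    def resolved_dropout(self) -> float:
        if self.dropout_rate is not None:
            return self.dropout_rate
        return DEFAULT_DROPOUT["mlp" if self.family == "mlp" else "sequence"]

    def to_yaml(self, stream: IO | None = None) -> str | None:
        return yaml.safe_dump(asdict(self), stream, sort_keys=True)

    @classmethod
    def from_yaml(cls, source: str | IO) -> "EncoderConfig":
        data = yaml.safe_load(source)
        return cls(**data)


class Encoder(Module):
    """Base encoder; subclasses set ``output_dim`` and ``accepts_sequences``."""

    accepts_sequences = True

    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        self.output_dim: int = 0

    def forward(self, x: Tensor, mask: Tensor | None = None) -> Tensor:
        raise NotImplementedError

    __call__ = lambda self, x, mask=None: self.forward(x, mask)


# ----------------------------------------------------------------------- MLP


class MLPEncoder(Encoder):
    """Per hidden layer: affine -> batch norm -> ReLU -> dropout; then a
    final affine projection to ``projection_dim``."""

    accepts_sequences = False

    def __init__(self, config: EncoderConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        drop_rng = np.random.default_rng((config.seed + 1) * 104729)
        dims = [config.input_dim] + [config.hidden_units] * config.num_hidden_layers
        self.hidden = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.norms = [BatchNorm1d(config.hidden_units) for _ in self.hidden]
        self.drops = [Dropout(config.resolved_dropout, drop_rng) for _ in self.hidden]
        self.project = Linear(config.hidden_units, config.projection_dim, rng)
        self.output_dim = config.projection_dim

    def forward(self, x: Tensor, mask: Tensor | None = None) -> Tensor:
        if x.ndim != 2:
            raise InputError(f"MLP expects a (batch, D) input, got ndim={x.ndim}")
        if x.shape[1] != self.config.input_dim:
            raise InputError(
                f"input dimension {x.shape[1]} != configured {self.config.input_dim}"
            )
        h = x
        for lin, bn, drop in zip(self.hidden, self.norms, self.drops):
            h = drop(ad.relu(bn(lin(h))))
        return self.project(h)


# ------------------------------------------------------------------ recurrent


class _LSTMCell(Module):
    """Fused-gate LSTM cell; gate order i, f, g, o."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Parameter(glorot(rng, input_dim, 4 * hidden))
        self.wh = Parameter(glorot(rng, hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.bias = Parameter(b)

    def run(self, x: Tensor, mask: np.ndarray) -> list[Tensor]:
        """Return the list of hidden states h_1..h_L (each (B, H))."""
        B, L, _ = x.shape
        H = self.hidden
        xp = x @ self.wx + self.bias  # (B, L, 4H), projected once
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        states = []
        for t in range(L):
            z = xp[:, t, :] + h @ self.wh
            i = ad.sigmoid(z[:, :H])
            f = ad.sigmoid(z[:, H: 2 * H])
            g = ad.tanh(z[:, 2 * H: 3 * H])
            o = ad.sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * ad.tanh(c_new)
            m = Tensor(mask[:, t: t + 1])
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            states.append(h)
        return states


class _GRUCell(Module):
    """GRU cell with update/reset gates and candidate state."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Parameter(glorot(rng, input_dim, 3 * hidden))
        self.wh_zr = Parameter(glorot(rng, hidden, 2 * hidden))
        self.wh_n = Parameter(glorot(rng, hidden, hidden))
        self.bias = Parameter(np.zeros(3 * hidden))

    def run(self, x: Tensor, mask: np.ndarray) -> list[Tensor]:
        B, L, _ = x.shape
        H = self.hidden
        xp = x @ self.wx + self.bias  # (B, L, 3H)
        h = Tensor(np.zeros((B, H)))
        states = []
        for t in range(L):
            xt = xp[:, t, :]
            zr = xt[:, : 2 * H] + h @ self.wh_zr
            z = ad.sigmoid(zr[:, :H])
            r = ad.sigmoid(zr[:, H:])
            n = ad.tanh(xt[:, 2 * H:] + (r * h) @ self.wh_n)
            h_new = (1.0 - z) * n + z * h
            m = Tensor(mask[:, t: t + 1])
            h = m * h_new + (1.0 - m) * h
            states.append(h)
        return states


class AttentionPool(Module):
    """Additive self-attention with a single learned scoring vector.

    Produces a convex combination of the hidden states; masked positions are
    excluded from the softmax.  The most recent weights are kept (as numpy)
    in ``last_weights`` for inspection.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.score = Parameter(glorot(rng, dim, 1, shape=(dim,)))
        self.last_weights: np.ndarray | None = None

    def __call__(self, states: Tensor, mask: np.ndarray) -> Tensor:
        if states.shape[1] < 1:
            raise InputError("attention pool needs at least one position")
        scores = states @ self.score  # (B, L)
        shift = Tensor(scores.data.max(axis=1, keepdims=True))  # detached max
        e = ad.exp(scores - shift) * Tensor(mask)
        denom = e.sum(axis=1, keepdims=True)
        alpha = e / denom
        self.last_weights = alpha.data.copy()
        B, L = alpha.shape
        return (alpha.reshape(B, L, 1) * states).sum(axis=1)


def _stack_states(states: list[Tensor]) -> Tensor:
    """(list of (B, H)) -> (B, L, H)."""
    B, H = states[0].shape
    return ad.concat([s.reshape(B, 1, H) for s in states], axis=1)


class RecurrentEncoder(Encoder):
    """LSTM/GRU encoder, optionally bidirectional and/or attention-pooled.

    Readout: final hidden state (concatenated final forward and backward
    states when bidirectional); attention variants instead return the
    attention-weighted sum over all (bi)hidden states.
    """

    def __init__(self, config: EncoderConfig, kind: str, bidirectional: bool,
                 attention: bool, input_dim: int | None = None):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        drop_rng = np.random.default_rng((config.seed + 1) * 104729)
        D = input_dim if input_dim is not None else config.input_dim
        H = config.hidden_units
        cell_cls = _LSTMCell if kind == "lstm" else _GRUCell
        self.fwd = cell_cls(D, H, rng)
        self.bwd = cell_cls(D, H, rng) if bidirectional else None
        self.bidirectional = bidirectional
        self.output_dim = 2 * H if bidirectional else H
        self.attention = AttentionPool(self.output_dim, rng) if attention else None
        self.dropout = Dropout(config.resolved_dropout, drop_rng)

    def forward(self, x: Tensor, mask: Tensor | np.ndarray | None = None) -> Tensor:
        if x.ndim != 3:
            raise InputError(f"sequence encoder expects (batch, L, D), got ndim={x.ndim}")
        if x.shape[1] < 1:
            raise InputError("empty sequence")
        B, L, _ = x.shape
        m = np.ones((B, L)) if mask is None else np.asarray(
            mask.data if isinstance(mask, Tensor) else mask, dtype=np.float64
        )
        fwd_states = self.fwd.run(x, m)
        if self.bwd is not None:
            # reverse time; reversed mask keeps the state frozen across the
            # tail padding until real tokens begin
            x_rev = x[:, ::-1, :]
            bwd_states = self.bwd.run(x_rev, m[:, ::-1])
            if self.attention is not None:
                # align backward state t with forward state t
                states = _stack_states(
                    [ad.concat([f, b], axis=1)
                     for f, b in zip(fwd_states, reversed(bwd_states))]
                )
                out = self.attention(states, m)
            else:
                out = ad.concat([fwd_states[-1], bwd_states[-1]], axis=1)
        else:
            if self.attention is not None:
                out = self.attention(_stack_states(fwd_states), m)
            else:
                out = fwd_states[-1]
        return self.dropout(out)


# ------------------------------------------------------------------------ CNN


class Conv1d(Module):
    """1-d convolution over the token axis: unit stride, no padding."""

    def __init__(self, input_dim: int, filters: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        self.filters = filters
        self.weight = Parameter(
            glorot(rng, kernel_size * input_dim, filters,
                   shape=(kernel_size, input_dim, filters))
        )
        self.bias = Parameter(np.zeros(filters))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        w = self.kernel_size
        if L < w:
            raise InputError(
                f"sequence length {L} is below the minimum of {w} "
                f"(the kernel size) required by the convolution"
            )
        L_out = L - w + 1
        out = x[:, 0:L_out, :] @ self.weight[0]
        for k in range(1, w):
            out = out + x[:, k: k + L_out, :] @ self.weight[k]
        return out + self.bias

    def output_lengths(self, lengths: np.ndarray) -> np.ndarray:
        return np.maximum(lengths - self.kernel_size + 1, 0)


def masked_mean_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over valid positions of a (B, L, F) tensor; mask is (B, L)."""
    counts = mask.sum(axis=1, keepdims=True)
    if np.any(counts == 0):
        raise InputError("mean-pool over a fully masked sequence")
    m = Tensor(mask[:, :, None])
    return (x * m).sum(axis=1) / Tensor(counts)


class CNNEncoder(Encoder):
    """Convolution + ReLU + mean-pooling over positions -> (B, K)."""

    def __init__(self, config: EncoderConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        drop_rng = np.random.default_rng((config.seed + 1) * 104729)
        self.conv = Conv1d(config.input_dim, config.cnn_filters, config.kernel_size, rng)
        self.dropout = Dropout(config.resolved_dropout, drop_rng)
        self.output_dim = config.cnn_filters

    def _conv_mask(self, mask: np.ndarray, L_out: int) -> np.ndarray:
        lengths = mask.sum(axis=1).astype(int)
        valid = self.conv.output_lengths(lengths)
        if np.any(valid < 1):
            raise InputError(
                f"every sequence must have at least {self.conv.kernel_size} "
                f"tokens (the kernel size) for the convolution"
            )
        out = np.zeros((mask.shape[0], L_out))
        for i, v in enumerate(valid):
            out[i, :v] = 1.0
        return out

    def forward(self, x: Tensor, mask: Tensor | np.ndarray | None = None) -> Tensor:
        if x.ndim != 3:
            raise InputError(f"CNN expects (batch, L, D), got ndim={x.ndim}")
        B, L, _ = x.shape
        m = np.ones((B, L)) if mask is None else np.asarray(
            mask.data if isinstance(mask, Tensor) else mask, dtype=np.float64
        )
        feats = ad.relu(self.conv(x))
        conv_mask = self._conv_mask(m, feats.shape[1])
        return self.dropout(masked_mean_pool(feats, conv_mask))


class CNNLSTMEncoder(Encoder):
    """CNN feature sequence (no pooling) fed into an LSTM; output dim = H."""

    def __init__(self, config: EncoderConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        drop_rng = np.random.default_rng((config.seed + 1) * 104729)
        self.conv = Conv1d(config.input_dim, config.cnn_filters, config.kernel_size, rng)
        self.lstm = _LSTMCell(config.cnn_filters, config.hidden_units, rng)
        self.dropout = Dropout(config.resolved_dropout, drop_rng)
        self.output_dim = config.hidden_units

    def forward(self, x: Tensor, mask: Tensor | np.ndarray | None = None) -> Tensor:
        if x.ndim != 3:
            raise InputError(f"CNN-LSTM expects (batch, L, D), got ndim={x.ndim}")
        B, L, _ = x.shape
        m = np.ones((B, L)) if mask is None else np.asarray(
            mask.data if isinstance(mask, Tensor) else mask, dtype=np.float64
        )
        feats = ad.relu(self.conv(x))
        L_out = feats.shape[1]
        lengths = m.sum(axis=1).astype(int)
        valid = self.conv.output_lengths(lengths)
        if np.any(valid < 1):
            raise InputError(
                f"every sequence must have at least {self.conv.kernel_size} "
                f"tokens (the kernel size) for the convolution"
            )
        conv_mask = np.zeros((B, L_out))
        for i, v in enumerate(valid):
            conv_mask[i, :v] = 1.0
        states = self.lstm.run(feats, conv_mask)
        return self.dropout(states[-1])


# ------------------------------------------------------------------- registry


def _recurrent_factory(kind: str, bidirectional: bool, attention: bool):
    def make(config: EncoderConfig) -> Encoder:
        return RecurrentEncoder(config, kind, bidirectional, attention)

    return make


ENCODER_REGISTRY: dict[str, object] = {
    "mlp": MLPEncoder,
    "lstm": _recurrent_factory("lstm", False, False),
    "gru": _recurrent_factory("gru", False, False),
    "bilstm": _recurrent_factory("lstm", True, False),
    "bigru": _recurrent_factory("gru", True, False),
    "lstm_att": _recurrent_factory("lstm", False, True),
    "gru_att": _recurrent_factory("gru", False, True),
    "bilstm_att": _recurrent_factory("lstm", True, True),
    "bigru_att": _recurrent_factory("gru", True, True),
    "cnn": CNNEncoder,
    "cnn_lstm": CNNLSTMEncoder,
}


def build_encoder(config: EncoderConfig) -> Encoder:
    """Instantiate an encoder from its config (seeded, reproducible)."""
    try:
        factory = ENCODER_REGISTRY[config.family]
    except KeyError as err:
        raise ConfigurationError(
            f"unknown encoder family {config.family!r}; known: {sorted(ENCODER_REGISTRY)}"
        ) from err
    return factory(config)


def encode(encoder: Encoder, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Numpy-in / numpy-out convenience around ``encoder.forward``.

    Accepts a single vector (D,), a single sequence (L, D), or a batch.
    """
    arr = np.asarray(x, dtype=np.float64)
    single = False
    if encoder.accepts_sequences:
        if arr.ndim == 2:
            arr = arr[None, :, :]
            single = True
        if arr.ndim != 3:
            raise InputError("sequence encoder expects (L, D) or (B, L, D)")
    else:
        if arr.ndim == 1:
            arr = arr[None, :]
            single = True
        if arr.ndim != 2:
            raise InputError("vector encoder expects (D,) or (B, D)")
    out = encoder.forward(Tensor(arr), mask).data
    return out[0] if single else out
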