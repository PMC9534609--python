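"""Reference numpy implementations of the classifier's building blocks.

These plain functions state the arithmetic of each block of the hybrid
classifier — LSTM gate cell, 1-D convolution channel, channel merge and
the temporal attention — in their simplest single-example form.  The
trainable model in :mod:`heartsel.acnn_lstm` implements the same
arithmetic batched on the autodiff engine; these functions serve as the
executable definition each block is tested against.

Gate equations of one LSTM step on input x_t with previous state
(h_{t-1}, c_{t-1}):

    z_t = tanh(W_z [h_{t-1}, x_t] + b_z)        (candidate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)     (input gate)
    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)     (forget gate)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)     (output gate)
    c_t = f_t * c_{t-1} + i_t * z_t
    h_t = o_t * tanh(c_t)

Attention over per-step states h_i = [h'_t ; c_t]:

    e_i = v_a^T tanh(W_r h_i + b),  w = softmax(e),  context = sum_j w_j h_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LSTMCellParams",
    "lstm_cell",
    "lstm_forward",
    "conv1d",
    "channel_forward",
    "merge_channels",
    "attention",
    "softmax_vec",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMCellParams:
    """Weights of one LSTM cell acting on the concatenation [h_prev, x_t]."""

    W_z: np.ndarray
    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    b_z: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @classmethod
    def zeros(cls, hidden_size: int, input_size: int) -> "LSTMCellParams":
        shape = (hidden_size, hidden_size + input_size)
        z = lambda: np.zeros(shape)
        b = lambda: np.zeros(hidden_size)
        return cls(z(), z(), z(), z(), b(), b(), b(), b())


def lstm_cell(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One gate step; returns (h_t, c_t)."""
    hx = np.concatenate([h_prev, x_t])
    if hx.shape[0] != params.W_z.shape[1]:
        raise ValueError(
            f"concatenated input length {hx.shape[0]} does not match weight "
            f"columns {params.W_z.shape[1]}"
        )
    z = np.tanh(params.W_z @ hx + params.b_z)
    i = _sigmoid(params.W_i @ hx + params.b_i)
    f = _sigmoid(params.W_f @ hx + params.b_f)
    o = _sigmoid(params.W_o @ hx + params.b_o)
    c_t = f * c_prev + i * z
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def lstm_forward(
    params: LSTMCellParams, xs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Run the cell over a (T, input_size) sequence from zero states.

    Returns (hs, cs), each of shape (T, hidden_size).
    """
    H = params.hidden_size
    h = np.zeros(H)
    c = np.zeros(H)
    hs, cs = [], []
    for t in range(xs.shape[0]):
        h, c = lstm_cell(params, xs[t], h, c)
        hs.append(h)
        cs.append(c)
    return np.array(hs), np.array(cs)


def conv1d(
    x: np.ndarray,
    kernel: np.ndarray,
    bias: np.ndarray | float = 0.0,
    padding: str = "same",
    activation=None,
) -> np.ndarray:
    """1-D convolution over the time axis of a (T, C_in) sequence.

    kernel has shape (K, C_in, C_out); ``same`` padding keeps the output
    length at T (zero padding (K-1)//2 left, K//2 right), ``valid`` gives
    T - K + 1.  Returns (T_out, C_out).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T  # (T,) -> (T, 1)
    if kernel.ndim == 1:
        kernel = kernel[:, None, None]
    K, c_in, c_out = kernel.shape
    if x.shape[1] != c_in:
        raise ValueError(f"input channels {x.shape[1]} != kernel channels {c_in}")
    if padding == "same":
        x = np.pad(x, (((K - 1) // 2, K // 2), (0, 0)))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    T_out = x.shape[0] - K + 1
    if T_out < 1:
        raise ValueError("kernel longer than (padded) sequence")
    out = np.zeros((T_out, c_out))
    for k in range(K):
        out += x[k : k + T_out] @ kernel[k]
    out = out + bias
    return activation(out) if activation is not None else out


def channel_forward(
    x: np.ndarray,
    kernel: np.ndarray,
    bias: np.ndarray,
    lstm_params: LSTMCellParams,
) -> np.ndarray:
    """One channel: ReLU conv map concatenated with the LSTM hidden sequence.

    Output shape (T, num_filters + lstm_hidden).
    """
    conv_out = conv1d(x, kernel, bias, padding="same", activation=lambda v: np.maximum(v, 0.0))
    hs, _ = lstm_forward(lstm_params, x)
    return np.concatenate([conv_out, hs], axis=1)


def merge_channels(channel_outputs: list[np.ndarray]) -> np.ndarray:
    """Max-pool each channel over time and concatenate the pooled vectors.

    The first half of the channels forms the conv-dominant group (C_out),
    the second half the LSTM-dominant group (W_out); the merged hidden
    vector is their concatenation, so for four channels each pooling to
    length 64 the result has length 256.
    """
    pooled = [np.asarray(c).max(axis=0) for c in channel_outputs]
    return np.concatenate(pooled)


def softmax_vec(e: np.ndarray) -> np.ndarray:
    z = np.exp(e - np.max(e))
    return z / z.sum()


def attention(
    h_seq: np.ndarray,
    c_seq: np.ndarray,
    v_a: np.ndarray,
    W_r: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal attention over per-step states h_i = [h'_t ; c_t].

    Returns (weights, context); weights lie on the probability simplex.
    """
    if h_seq.shape[0] < 1:
        raise ValueError("attention requires at least one time step")
    h_i = np.concatenate([h_seq, c_seq], axis=1)  # (T, 2H)
    e = np.tanh(h_i @ W_r.T + b) @ v_a  # (T,)
    w = softmax_vec(e)
    context = w @ h_i
    return w, context
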