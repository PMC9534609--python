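"""Four-channel attention CNN-LSTM classifier for selected clinical features.

The m selected features of one record are treated as a length-m sequence:
each scalar feature value is linearly embedded to ``embed_dim``, and the
embedded sequence is fed to four parallel channels.  Each channel
concatenates a same-padded 1-D convolutional feature map (ReLU, kernel
sizes 2/3/4/5 by default) with the hidden-state sequence of an LSTM run
over the same embedding, then max-pools over the sequence.  The pooled
vectors of the conv-dominant first two channels form C_out and those of
the LSTM-dominant last two form W_out; their concatenation is the merged
hidden vector h.  A temporal attention over the first channel's per-step
states h_i = [h'_t ; c_t] produces a context vector that is concatenated
with h before the dense softmax head.

Training minimises cross-entropy with Adam, mini-batches, optional
dropout on the merged representation and early stopping on a stratified
validation split.  All randomness (initialisation, batching, dropout,
split) flows from the configured seeds, so a fixed seed reproduces the
final loss bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .autodiff import Adam, Tensor, concat, softmax, softmax_cross_entropy, stack

__all__ = [
    "ChannelConfig",
    "ModelConfig",
    "TrainConfig",
    "ACNNLSTMClassifier",
    "TrainingResults",
]


@dataclass
class ChannelConfig:
    kernel_size: int
    num_filters: int = 32
    lstm_hidden: int = 32

    def __post_init__(self) -> None:
        if min(self.kernel_size, self.num_filters, self.lstm_hidden) < 1:
            raise ValueError("channel sizes must be positive")


def _default_channels() -> list[ChannelConfig]:
    return [ChannelConfig(kernel_size=k) for k in (2, 3, 4, 5)]


@dataclass
class ModelConfig:
    """Architecture sizes; the defaults give a ~60k-parameter model."""

    embed_dim: int = 16
    channels: list[ChannelConfig] = field(default_factory=_default_channels)
    attention_dim: int = 32
    num_classes: int = 2
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3  # decoupled L2; guards against memorising noise features
    early_stop_patience: int = 20  # 0 disables early stopping
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")


@dataclass
class TrainingResults:
    """Loss history and a handle back to the fitted classifier."""

    model: "ACNNLSTMClassifier"
    train_loss: list[float]
    val_loss: list[float]
    stopped_epoch: int

    def summary(self) -> str:
        lines = [
            "Attention CNN-LSTM training",
            "=" * 40,
            f"epochs run:        {self.stopped_epoch}",
            f"final train loss:  {self.train_loss[-1]:.6f}",
        ]
        if self.val_loss:
            lines.append(f"best val loss:     {min(self.val_loss):.6f}")
        lines.append(f"parameters:        {self.model.n_parameters}")
        return "\n".join(lines)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ACNNLSTMClassifier:
    """Trainable four-channel attention CNN-LSTM for tabular input.

    The parameter shapes depend on the number of input features m, so the
    parameters are built lazily on the first ``fit`` (or an explicit
    ``build(m)``).
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.m: int | None = None
        self._params: dict[str, Tensor] = {}

    # -- parameters --------------------------------------------------------
    def build(self, m: int) -> None:
        cfg = self.config
        if m < 1:
            raise ValueError("need at least one input feature")
        rng = np.random.default_rng(cfg.seed)
        P: dict[str, Tensor] = {}

        def param(name: str, value: np.ndarray) -> None:
            P[name] = Tensor(value, requires_grad=True)

        E = cfg.embed_dim
        param("W_e", _glorot(rng, (m, E)))
        param("b_e", np.zeros((m, E)))
        feat_len = 0
        for ci, ch in enumerate(cfg.channels):
            K, F, H = ch.kernel_size, ch.num_filters, ch.lstm_hidden
            param(f"conv_W{ci}", _glorot(rng, (K, E, F)) / np.sqrt(K))
            param(f"conv_b{ci}", np.zeros(F))
            for gate in "zifo":
                param(f"lstm_W{gate}{ci}", _glorot(rng, (H + E, H)))
                # forget gate bias 1.0: standard stabilisation of early training
                param(f"lstm_b{gate}{ci}", np.ones(H) if gate == "f" else np.zeros(H))
            feat_len += F + H
        H0 = cfg.channels[0].lstm_hidden
        A = cfg.attention_dim
        param("att_Wr", _glorot(rng, (2 * H0, A)))
        param("att_b", np.zeros(A))
        param("att_va", _glorot(rng, (A, 1)))
        feat_len += 2 * H0
        param("head_W", _glorot(rng, (feat_len, cfg.num_classes)))
        param("head_b", np.zeros(cfg.num_classes))
        self._params = P
        self.m = m

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self._params[k].data = v.copy()

    def save(self, path) -> None:
        """Checkpoint: one .npz with the weights plus the input width m."""
        if self.m is None:
            raise RuntimeError("nothing to save: model not built")
        np.savez(path, __m__=np.array(self.m), **self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.build(int(data["__m__"]))
            self.set_weights({k: data[k] for k in data.files if k != "__m__"})

    # -- forward -----------------------------------------------------------
    def _lstm(self, emb: Tensor, ci: int, B: int):
        """Run channel ci's LSTM over the embedded sequence.

        Returns (hidden sequence tensors, cell sequence tensors).
        """
        P = self._params
        H = self.config.channels[ci].lstm_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        hs, cs = [], []
        for t in range(self.m):
            xt = emb[:, t, :]
            cat = concat([h, xt], axis=1)
            z = (cat @ P[f"lstm_Wz{ci}"] + P[f"lstm_bz{ci}"]).tanh()
            i = (cat @ P[f"lstm_Wi{ci}"] + P[f"lstm_bi{ci}"]).sigmoid()
            f = (cat @ P[f"lstm_Wf{ci}"] + P[f"lstm_bf{ci}"]).sigmoid()
            o = (cat @ P[f"lstm_Wo{ci}"] + P[f"lstm_bo{ci}"]).sigmoid()
            c = f * c + i * z
            h = o * c.tanh()
            hs.append(h)
            cs.append(c)
        return hs, cs

    def _forward(self, X: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a (B, m) batch."""
        if self.m is None:
            raise RuntimeError("model not built; call fit() or build(m)")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.m:
            raise ValueError(f"expected input of shape (B, {self.m}), got {X.shape}")
        P = self._params
        B = X.shape[0]
        x3 = Tensor(X[:, :, None])
        emb = x3 * P["W_e"] + P["b_e"]  # (B, m, E)

        pooled = []
        att_states = None
        for ci, ch in enumerate(self.config.channels):
            K = ch.kernel_size
            pad = emb.pad_axis1((K - 1) // 2, K // 2)
            conv = pad[:, 0 : 0 + self.m, :] @ P[f"conv_W{ci}"][0]
            for k in range(1, K):
                conv = conv + pad[:, k : k + self.m, :] @ P[f"conv_W{ci}"][k]
            conv = (conv + P[f"conv_b{ci}"]).relu()  # (B, m, F)
            hs, cs = self._lstm(emb, ci, B)
            h_seq = stack(hs, axis=1)  # (B, m, H)
            if ci == 0:
                att_states = concat([h_seq, stack(cs, axis=1)], axis=2)  # (B, m, 2H)
            pooled.append(concat([conv, h_seq], axis=2).max_axis(1))

        merged = concat(pooled, axis=1)  # C_out (+) W_out
        scores = (att_states @ P["att_Wr"] + P["att_b"]).tanh() @ P["att_va"]
        w = scores.softmax_axis(1)  # (B, m, 1)
        context = (w * att_states).sum(axis=1)  # (B, 2H)
        feat = concat([merged, context], axis=1)
        if training and self.config.dropout > 0.0:
            keep = 1.0 - self.config.dropout
            mask = (rng.random(feat.shape) < keep) / keep
            feat = feat * Tensor(mask)
        return feat @ P["head_W"] + P["head_b"]

    # -- public API --------------------------------------------------------
    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        """Mean cross-entropy of the (inference-mode) forward pass."""
        return softmax_cross_entropy(self._forward(X, training=False), y)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self._forward(np.atleast_2d(X), training=False)
        return softmax(logits.data, axis=-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-step attention weights, shape (B, m); rows sum to 1."""
        P = self._params
        X = np.atleast_2d(np.asarray(X, dtype=float))
        B = X.shape[0]
        emb = Tensor(X[:, :, None]) * P["W_e"] + P["b_e"]
        hs, cs = self._lstm(emb, 0, B)
        att = concat([stack(hs, axis=1), stack(cs, axis=1)], axis=2)
        scores = (att @ P["att_Wr"] + P["att_b"]).tanh() @ P["att_va"]
        return scores.softmax_axis(1).data[:, :, 0]

    def fit(
        self, X: np.ndarray, y: np.ndarray, train_config: TrainConfig | None = None
    ) -> TrainingResults:
        """Train with Adam + early stopping; returns the loss history."""
        cfg = train_config or TrainConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.m is None:
            self.build(X.shape[1])
        rng = np.random.default_rng(cfg.seed + 7 * self.config.seed)

        use_val = cfg.early_stop_patience > 0 and cfg.val_fraction > 0.0
        if use_val:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=cfg.val_fraction, stratify=y,
                random_state=cfg.seed % (2**31),
            )
        else:
            X_tr, y_tr = X, y
            X_val = y_val = None

        opt = Adam(self.parameters(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
        train_hist: list[float] = []
        val_hist: list[float] = []
        best_val = np.inf
        best_weights = None
        patience_left = cfg.early_stop_patience
        n = X_tr.shape[0]
        epoch = 0
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self._forward(X_tr[idx], training=True, rng=rng)
                loss = softmax_cross_entropy(logits, y_tr[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses.append(float(loss.data))
            train_hist.append(float(np.mean(batch_losses)))
            if use_val:
                v = float(self.loss(X_val, y_val).data)
                val_hist.append(v)
                if v < best_val - 1e-6:
                    best_val = v
                    best_weights = self.get_weights()
                    patience_left = cfg.early_stop_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return TrainingResults(self, train_hist, val_hist, epoch)
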