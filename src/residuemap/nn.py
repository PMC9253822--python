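"""Minimal numpy layer stack: the 1D-CNN and channel-attention 1D-CNN_CA.

A pixel's feature vector (length ``n_f``, one channel) passes through

    Conv1D(512 filters, kernel 3, same padding) -> ReLU
    -> [channel attention]            (1D-CNN_CA only)
    -> Flatten (n_f x 512) -> Dropout 0.4
    -> Dense 2048 (ReLU) -> Dense 1024 (ReLU) -> Dense n_class (linear)
    -> Softmax

The channel-attention module gates each of the 512 channels with a weight in
(0, 1) computed from global average and global maximum pooling over the
length axis, both passed through one shared two-layer perceptron (bottleneck
ratio 8, ReLU hidden) whose outputs are added and squashed by a sigmoid:

    M(F) = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F)))
    F_c  = M(F) * F        (broadcast along the length axis)

Training is softmax cross-entropy with Adam at the configured initial
learning rate (0.01 by default), mini-batches of 20, fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit as sigmoid


@dataclass
class NetworkConfig:
    """Hyperparameters; defaults are the full-size published configuration."""

    n_f: int
    n_class: int
    conv_filters: int = 512
    kernel_size: int = 3
    dropout: float = 0.4
    dense_widths: tuple[int, int] = (2048, 1024)
    epochs: int = 150
    batch_size: int = 20
    learning_rate: float = 0.01
    attention: bool = True
    bottleneck_ratio: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f < 1:
            raise ValueError("n_f must be >= 1")
        if self.n_class < 2:
            raise ValueError("n_class must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def fast(cls, n_f: int, n_class: int, **overrides) -> "NetworkConfig":
        """Reduced widths/epochs for quick experiments and the test suite."""
        params = dict(
            conv_filters=64, dense_widths=(256, 128), epochs=30,
        )
        params.update(overrides)
        return cls(n_f=n_f, n_class=n_class, **params)


@dataclass
class AttentionBlock:
    """Shared two-layer perceptron of the channel-attention module."""

    W1: np.ndarray  # (C, C // ratio)
    b1: np.ndarray
    W2: np.ndarray  # (C // ratio, C)
    b2: np.ndarray

    @classmethod
    def init(
        cls, channels: int, ratio: int, rng: np.random.Generator
    ) -> "AttentionBlock":
        hidden = max(1, channels // ratio)
        w1 = rng.normal(0, np.sqrt(2.0 / channels), size=(channels, hidden))
        w2 = rng.normal(0, np.sqrt(2.0 / hidden), size=(hidden, channels))
        return cls(w1, np.zeros(hidden), w2, np.zeros(channels))

    def mlp(self, pooled: np.ndarray) -> np.ndarray:
        return np.maximum(pooled @ self.W1 + self.b1, 0.0) @ self.W2 + self.b2


def cam_forward(
    F: np.ndarray, block: AttentionBlock, return_weights: bool = False
):
    """Channel attention: F_c = M(F) * F with per-channel M(F) in (0, 1).

    ``F`` has shape (batch, length, channels); pooling is over the length
    axis and the gate broadcasts back along it.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim == 2:  # single example (length, channels)
        Fc, M = cam_forward(F[None], block, return_weights=True)
        return (Fc[0], M[0]) if return_weights else Fc[0]
    if F.ndim != 3:
        raise ValueError("F must be (batch, length, channels)")
    if F.shape[2] != block.W1.shape[0]:
        raise ValueError(
            f"channel count {F.shape[2]} does not match attention block "
            f"({block.W1.shape[0]} channels)"
        )
    avg = F.mean(axis=1)
    mx = F.max(axis=1)
    M = sigmoid(block.mlp(avg) + block.mlp(mx))
    Fc = F * M[:, None, :]
    return (Fc, M) if return_weights else Fc


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_params(config: NetworkConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    C, K = config.conv_filters, config.kernel_size
    d1, d2 = config.dense_widths
    flat = config.n_f * C
    params: dict[str, np.ndarray] = {
        "conv_W": _he(rng, K, (K, C)),
        "conv_b": np.zeros(C),
        "W1": _he(rng, flat, (flat, d1)),
        "b1": np.zeros(d1),
        "W2": _he(rng, d1, (d1, d2)),
        "b2": np.zeros(d2),
        "W3": _he(rng, d2, (d2, config.n_class)),
        "b3": np.zeros(config.n_class),
    }
    if config.attention:
        att = AttentionBlock.init(C, config.bottleneck_ratio, rng)
        params.update(
            att_W1=att.W1, att_b1=att.b1, att_W2=att.W2, att_b2=att.b2
        )
    return params


def _conv1d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (B, T) with one channel -> (B, T, C); zero same-padding."""
    K = W.shape[0]
    pad = K // 2
    xp = np.pad(x, ((0, 0), (pad, pad)))
    T = x.shape[1]
    Xs = np.stack([xp[:, k : k + T] for k in range(K)], axis=2)  # (B, T, K)
    return Xs @ W + b, Xs


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def network_forward(
    x: np.ndarray,
    config: NetworkConfig,
    params: Mapping[str, np.ndarray] | None = None,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
):
    """Forward pass; returns (probabilities, cache of intermediates).

    ``cache['logits']`` holds the pre-softmax dense output; every row of the
    returned probabilities sums to one.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None]
    if x.shape[1] != config.n_f:
        raise ValueError(f"expected feature vectors of length {config.n_f}")
    if params is None:
        params = init_params(config)
    cache: dict = {"x": x, "params": params}
    Zc, Xs = _conv1d_same(x, params["conv_W"], params["conv_b"])
    F = np.maximum(Zc, 0.0)
    cache.update(Zc=Zc, Xs=Xs, F=F)
    if config.attention:
        block = AttentionBlock(
            params["att_W1"], params["att_b1"], params["att_W2"], params["att_b2"]
        )
        avg, mx = F.mean(axis=1), F.max(axis=1)
        idx = F.argmax(axis=1)
        ha = np.maximum(avg @ block.W1 + block.b1, 0.0)
        hm = np.maximum(mx @ block.W1 + block.b1, 0.0)
        s = ha @ block.W2 + block.b2 + hm @ block.W2 + block.b2
        M = sigmoid(s)
        Fc = F * M[:, None, :]
        cache.update(avg=avg, mx=mx, idx=idx, ha=ha, hm=hm, M=M)
    else:
        Fc = F
    flat = Fc.reshape(x.shape[0], -1)
    if train and config.dropout > 0:
        rng = dropout_rng or np.random.default_rng(config.seed)
        mask = rng.random(flat.shape) >= config.dropout
        flat = flat * mask / (1.0 - config.dropout)
        cache["drop_mask"] = mask
    Z1 = flat @ params["W1"] + params["b1"]
    A1 = np.maximum(Z1, 0.0)
    Z2 = A1 @ params["W2"] + params["b2"]
    A2 = np.maximum(Z2, 0.0)
    logits = A2 @ params["W3"] + params["b3"]
    probs = _softmax(logits)
    cache.update(flat=flat, Z1=Z1, A1=A1, Z2=Z2, A2=A2, logits=logits)
    return probs, cache


def _backward(
    probs: np.ndarray, onehot: np.ndarray, cache: dict, config: NetworkConfig
) -> dict[str, np.ndarray]:
    params = cache["params"]
    B = probs.shape[0]
    grads: dict[str, np.ndarray] = {}
    dlogits = (probs - onehot) / B
    grads["W3"] = cache["A2"].T @ dlogits
    grads["b3"] = dlogits.sum(axis=0)
    dA2 = dlogits @ params["W3"].T
    dZ2 = dA2 * (cache["Z2"] > 0)
    grads["W2"] = cache["A1"].T @ dZ2
    grads["b2"] = dZ2.sum(axis=0)
    dA1 = dZ2 @ params["W2"].T
    dZ1 = dA1 * (cache["Z1"] > 0)
    grads["W1"] = cache["flat"].T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    dflat = dZ1 @ params["W1"].T
    if "drop_mask" in cache:
        dflat = dflat * cache["drop_mask"] / (1.0 - config.dropout)
    F = cache["F"]
    dFc = dflat.reshape(F.shape)
    if config.attention:
        M, avg, mx = cache["M"], cache["avg"], cache["mx"]
        ha, hm, idx = cache["ha"], cache["hm"], cache["idx"]
        W1a, W2a = params["att_W1"], params["att_W2"]
        dM = (dFc * F).sum(axis=1)
        dF = dFc * M[:, None, :]
        ds = dM * M * (1.0 - M)
        dha = (ds @ W2a.T) * (ha > 0)
        dhm = (ds @ W2a.T) * (hm > 0)
        grads["att_W2"] = ha.T @ ds + hm.T @ ds
        grads["att_b2"] = 2.0 * ds.sum(axis=0)
        grads["att_W1"] = avg.T @ dha + mx.T @ dhm
        grads["att_b1"] = dha.sum(axis=0) + dhm.sum(axis=0)
        davg = dha @ W1a.T
        dmx = dhm @ W1a.T
        dF = dF + davg[:, None, :] / F.shape[1]
        from_max = np.zeros_like(F)
        np.put_along_axis(from_max, idx[:, None, :], dmx[:, None, :], axis=1)
        dF = dF + from_max
    else:
        dF = dFc
    dZc = dF * (cache["Zc"] > 0)
    grads["conv_W"] = np.einsum("btk,btc->kc", cache["Xs"], dZc)
    grads["conv_b"] = dZc.sum(axis=(0, 1))
    return grads


class AdamOptimizer:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


@dataclass
class OneDCNNClassifier:
    """Trainable wrapper with a scikit-learn-flavored fit/predict surface."""

    config: NetworkConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)
    classes_: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneDCNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        cfg = self.config
        if cfg.n_class != self.classes_.size:
            cfg = replace(cfg, n_class=int(self.classes_.size))
            self.config = cfg
        y_idx = np.searchsorted(self.classes_, y)
        onehot_full = np.eye(cfg.n_class)[y_idx]
        self.params = init_params(cfg)
        opt = AdamOptimizer(self.params, cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                probs, cache = network_forward(
                    X[sel], cfg, self.params, train=True, dropout_rng=rng
                )
                onehot = onehot_full[sel]
                eps = 1e-12
                epoch_loss -= float(
                    (onehot * np.log(probs + eps)).sum()
                )
                grads = _backward(probs, onehot, cache, cfg)
                opt.step(self.params, grads)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.config.n_class))
        for start in range(0, X.shape[0], chunk):
            probs, _ = network_forward(
                X[start : start + chunk], self.config, self.params
            )
            out[start : start + chunk] = probs
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
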