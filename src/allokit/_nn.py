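"""Minimal deterministic CNN used for contact-image classification.

Channels-last layout (batch, height, width, channels). Two strided 3x3
convolution stages with ReLU, one hidden dense layer, and a linear head;
trained with softmax cross-entropy and Adam. Small enough that CPU
training on contact images takes seconds, and written in plain numpy so
the input gradient needed for saliency attribution is exact and
deterministic for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int):
    """x: (B,H,W,C); w: (k,k,C,OC). Returns (out, patches)."""
    k = w.shape[0]
    win = sliding_window_view(x, (k, k), axis=(1, 2))      # (B,oh,ow,C,k,k)
    win = win[:, ::stride, ::stride]
    patches = win.transpose(0, 1, 2, 4, 5, 3).reshape(*win.shape[:3], -1)  # (B,oh,ow,k*k*C)
    # kernel flattened consistently with the (k, k, C) patch layout
    wmat = w.reshape(k * k * w.shape[2], w.shape[3])
    out = patches @ wmat + b
    return out, patches


def _conv_backward(grad_out: np.ndarray, patches: np.ndarray, w: np.ndarray,
                   x_shape: tuple, stride: int):
    """Returns (dx, dw, db)."""
    k, _, c, oc = w.shape
    wmat = w.reshape(k * k * c, oc)
    b_, oh, ow, _ = grad_out.shape
    dw = patches.reshape(-1, k * k * c).T @ grad_out.reshape(-1, oc)
    db = grad_out.sum(axis=(0, 1, 2))
    dpatch = (grad_out @ wmat.T).reshape(b_, oh, ow, k, k, c)
    dx = np.zeros(x_shape)
    for a in range(k):
        for bb in range(k):
            dx[:, a:a + oh * stride:stride, bb:bb + ow * stride:stride, :] += dpatch[:, :, :, a, bb, :]
    return dx, dw.reshape(w.shape), db


def _out_hw(n: int, k: int, stride: int) -> int:
    return (n - k) // stride + 1


class SmallCNN:
    """Two conv+downsample stages, hidden dense layer, softmax head."""

    def __init__(self, input_hw: int, n_classes: int, channels: tuple[int, int] = (8, 8),
                 kernel: int = 3, stride: int = 2, hidden: int = 32, seed: int = 0):
        self.input_hw = input_hw
        self.n_classes = n_classes
        self.kernel = kernel
        self.stride = stride
        self.channels = tuple(channels)
        self.hidden = hidden
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = kernel
        c1, c2 = self.channels
        h1 = _out_hw(input_hw, k, stride)
        h2 = _out_hw(h1, k, stride)
        if h2 < 1:
            raise ValueError("input too small for two conv stages")
        self.flat_dim = h2 * h2 * c2

        def he(shape, fan_in):
            return rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)

        self.params = {
            "w1": he((k, k, 1, c1), k * k), "b1": np.zeros(c1),
            "w2": he((k, k, c1, c2), k * k * c1), "b2": np.zeros(c2),
            "w3": he((self.flat_dim, hidden), self.flat_dim), "b3": np.zeros(hidden),
            "w4": he((hidden, n_classes), hidden), "b4": np.zeros(n_classes),
        }

    def describe(self) -> dict:
        return {"input_hw": self.input_hw, "n_classes": self.n_classes,
                "kernel": self.kernel, "stride": self.stride,
                "channels": list(self.channels), "hidden": self.hidden,
                "seed": self.seed,
                "n_parameters": int(sum(p.size for p in self.params.values()))}

    # forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, need_cache: bool = False):
        """x: (B, H, W) images in [0, 1]. Returns logits (B, n_classes)."""
        p = self.params
        x = np.ascontiguousarray(x, dtype=float)[..., None]           # (B,H,W,1)
        z1, pat1 = _conv_forward(x, p["w1"], p["b1"], self.stride)
        a1 = np.maximum(z1, 0.0)
        z2, pat2 = _conv_forward(a1, p["w2"], p["b2"], self.stride)
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(len(a2), -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["w4"] + p["b4"]
        if need_cache:
            cache = (x, z1, pat1, a1, z2, pat2, a2, z3, a3)
            return logits, cache
        return logits

    def backward(self, dlogits: np.ndarray, cache):
        """Gradients of sum(dlogits * logits) w.r.t. params and input."""
        p = self.params
        x, z1, pat1, a1, z2, pat2, a2, z3, a3 = cache
        grads = {}
        grads["w4"] = a3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["w4"].T
        dz3 = da3 * (z3 > 0)
        flat = a2.reshape(len(a2), -1)
        grads["w3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        da2 = dflat.reshape(a2.shape)
        dz2 = da2 * (z2 > 0)
        da1, grads["w2"], grads["b2"] = _conv_backward(dz2, pat2, p["w2"], a1.shape, self.stride)
        dz1 = da1 * (z1 > 0)
        dx, grads["w1"], grads["b1"] = _conv_backward(dz1, pat1, p["w1"], x.shape, self.stride)
        return grads, dx[..., 0]

    def input_gradient(self, image: np.ndarray, target_class: int) -> np.ndarray:
        """d logit[target] / d pixel for a single (H, W) image."""
        logits, cache = self.forward(image[None], need_cache=True)
        dlogits = np.zeros_like(logits)
        dlogits[0, target_class] = 1.0
        _, dx = self.backward(dlogits, cache)
        return dx[0]

    # persistence ----------------------------------------------------------

    def save(self, path) -> None:
        meta = self.describe()
        np.savez(path, __meta__=np.array([repr(meta)], dtype=object), **self.params)

    @classmethod
    def load(cls, path) -> "SmallCNN":
        import ast
        with np.load(path, allow_pickle=True) as data:
            meta = ast.literal_eval(str(data["__meta__"][0]))
            net = cls(meta["input_hw"], meta["n_classes"],
                      channels=tuple(meta["channels"]), kernel=meta["kernel"],
                      stride=meta["stride"], hidden=meta["hidden"], seed=meta["seed"])
            for key in net.params:
                net.params[key] = data[key]
        return net


class Adam:
    """Adaptive-moment optimizer with decoupled L2 weight decay."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            if self.weight_decay and key.startswith("w"):
                g = g + self.weight_decay * params[key]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean loss and gradient w.r.t. logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    n = len(labels)
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
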