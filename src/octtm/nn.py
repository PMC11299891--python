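"""A compact, fully deterministic CNN for binary patch classification.

Implements the forward and backward passes of a small convolutional network
(valid 3x3 convolutions via im2col, ReLU, 2x2 max-pooling, one dense hidden
layer with inverted dropout, and a single-logit output head) plus an Adam
optimizer, all in float32 NumPy.  With a fixed seed and fixed data order the
entire training trajectory is bit-reproducible on CPU, which the training
determinism guarantees elsewhere in the package rely on.

The loss is binary cross-entropy computed on the logit (log-sum-exp form),
so probabilities near 0/1 cannot overflow.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["PatchCNN", "DEFAULT_ARCH", "bce_with_logits", "sigmoid"]

DEFAULT_ARCH = {
    "input_size": [64, 64],
    "conv_blocks": [
        {"filters": 16, "kernel": 3},
        {"filters": 32, "kernel": 3},
    ],
    "dense_units": 64,
    "dropout": 0.25,
}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, stable for large |logit|."""
    z, y = np.asarray(logits, dtype=np.float64), np.asarray(y, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,Ho,Wo,C,k,k)
    win = win.transpose(0, 1, 2, 4, 5, 3)              # (N,Ho,Wo,k,k,C)
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, ho, wo, k * k * x.shape[3])


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class PatchCNN:
    """Patch -> TM-probability network with seeded initialization.

    Parameters
    ----------
    arch
        Architecture descriptor (see :data:`DEFAULT_ARCH`).  At least one
        conv block is required and the input edge must be >= 16 px.
    seed
        Seeds both parameter initialization and the dropout stream.
    """

    def __init__(self, arch: dict | None = None, seed: int = 0):
        arch = {**DEFAULT_ARCH, **(arch or {})}
        h, w = arch["input_size"]
        if h < 16 or w < 16:
            raise ValueError(f"input_size must be >= 16x16, got {(h, w)}")
        if not arch.get("conv_blocks"):
            raise ValueError("architecture needs at least one conv block")
        self.arch = arch
        self.seed = int(seed)
        self.input_size = (int(h), int(w))
        self.dropout = float(arch.get("dropout", 0.0))
        self._rng = np.random.default_rng(self.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_params()
        self._opt: _Adam | None = None

    # ---- construction ----------------------------------------------------
    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        h, w, c = *self.input_size, 1
        for i, blk in enumerate(self.arch["conv_blocks"]):
            k, f = int(blk["kernel"]), int(blk["filters"])
            fan_in = k * k * c
            self.params[f"Wc{i}"] = (
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, f)).astype(np.float32)
            )
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            h, w, c = (h - k + 1) // 2, (w - k + 1) // 2, f
            if h < 1 or w < 1:
                raise ValueError("input too small for the conv/pool stack")
        d = h * w * c
        u = int(self.arch["dense_units"])
        self.params["W1"] = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, u)).astype(np.float32)
        self.params["b1"] = np.zeros(u, dtype=np.float32)
        self.params["W2"] = rng.normal(0.0, np.sqrt(2.0 / u), size=(u, 1)).astype(np.float32)
        self.params["b2"] = np.zeros(1, dtype=np.float32)

    # ---- forward / backward ----------------------------------------------
    def _forward(self, x: np.ndarray, train: bool):
        """x: (N, H, W) in [0,1].  Returns (logits, cache)."""
        a = np.asarray(x, dtype=np.float32)[..., None]  # (N,H,W,1)
        cache: dict = {"acts": []}
        for i, blk in enumerate(self.arch["conv_blocks"]):
            k = int(blk["kernel"])
            cols = _im2col(a, k)
            z = cols @ self.params[f"Wc{i}"] + self.params[f"bc{i}"]
            r = np.maximum(z, 0.0)
            # 2x2 max-pool (odd trailing row/col cropped)
            n, ho, wo, f = r.shape
            hp, wp = ho // 2, wo // 2
            rc = r[:, : hp * 2, : wp * 2, :].reshape(n, hp, 2, wp, 2, f)
            p = rc.max(axis=(2, 4))
            cache["acts"].append({"cols": cols, "z": z, "r": r, "p": p, "k": k})
            a = p
        n = a.shape[0]
        flat = a.reshape(n, -1)
        h1 = flat @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(h1, 0.0)
        if train and self.dropout > 0.0:
            keep = (self._rng.random(a1.shape) >= self.dropout).astype(np.float32)
            a1d = a1 * keep / (1.0 - self.dropout)
        else:
            keep = None
            a1d = a1
        logits = (a1d @ self.params["W2"] + self.params["b2"])[:, 0]
        cache.update(flat=flat, h1=h1, a1d=a1d, keep=keep, pooled_shape=a.shape)
        return logits, cache

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        grads: dict[str, np.ndarray] = {}
        dl = dlogits[:, None].astype(np.float32)
        grads["W2"] = cache["a1d"].T @ dl
        grads["b2"] = dl.sum(axis=0)
        da1 = dl @ self.params["W2"].T
        if cache["keep"] is not None:
            da1 = da1 * cache["keep"] / (1.0 - self.dropout)
        dh1 = da1 * (cache["h1"] > 0)
        grads["W1"] = cache["flat"].T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        da = (dh1 @ self.params["W1"].T).reshape(cache["pooled_shape"])
        for i in range(len(self.arch["conv_blocks"]) - 1, -1, -1):
            ly = cache["acts"][i]
            r, k = ly["r"], ly["k"]
            n, ho, wo, f = r.shape
            hp, wp = ho // 2, wo // 2
            # route pool gradient to the argmax position(s)
            rc = r[:, : hp * 2, : wp * 2, :].reshape(n, hp, 2, wp, 2, f)
            is_max = rc == ly["p"][:, :, None, :, None, :]
            dr = np.zeros_like(r)
            drc = is_max * da[:, :, None, :, None, :]
            dr[:, : hp * 2, : wp * 2, :] = drc.reshape(n, hp * 2, wp * 2, f)
            dz = dr * (ly["z"] > 0)
            cols = ly["cols"]
            grads[f"Wc{i}"] = cols.reshape(-1, cols.shape[-1]).T @ dz.reshape(-1, f)
            grads[f"bc{i}"] = dz.sum(axis=(0, 1, 2))
            if i > 0:
                # full correlation with the flipped kernels propagates to input
                w = self.params[f"Wc{i}"]
                cin = cols.shape[-1] // (k * k)
                wk = w.reshape(k, k, cin, f)[::-1, ::-1]
                wt = np.ascontiguousarray(wk.transpose(0, 1, 3, 2)).reshape(k * k * f, cin)
                pad = k - 1
                dzp = np.pad(dz, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
                da = _im2col(dzp, k) @ wt
        return grads

    # ---- public API -------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """TM probabilities for patches ``x`` of shape (N, H, W) in [0,1]."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        out = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            logits, _ = self._forward(x[i : i + batch_size], train=False)
            out[i : i + len(logits)] = sigmoid(logits.astype(np.float64))
        return out

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float = 1e-3) -> float:
        """One Adam step on a minibatch; returns the batch BCE loss."""
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if self._opt is None or self._opt.lr != lr:
            opt = _Adam(self.params, lr)
            if self._opt is not None:  # keep moments across lr changes
                opt.m, opt.v, opt.t = self._opt.m, self._opt.v, self._opt.t
            self._opt = opt
        logits, cache = self._forward(x, train=True)
        loss = bce_with_logits(logits, y)
        dlogits = (sigmoid(logits) - y) / len(y)
        grads = self._backward(cache, dlogits)
        self._opt.step(self.params, grads)
        return loss

    # ---- serialization ----------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "arch.json").write_text(
            json.dumps({"arch": self.arch, "seed": self.seed}, indent=1)
        )
        np.savez(directory / "weights.npz", **self.params)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PatchCNN":
        directory = Path(directory)
        meta = json.loads((directory / "arch.json").read_text())
        model = cls(meta["arch"], seed=meta["seed"])
        with np.load(directory / "weights.npz") as data:
            for k in model.params:
                model.params[k] = data[k]
        return model
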