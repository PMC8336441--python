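"""Minimal NumPy neural-network engine for the pathway-image classifier.

Implements exactly the fixed architecture used for long-term-survival
classification: two 3x3 convolutions (32 then 64 filters, ReLU), one 4x2
max-pool, dropout, flatten (optionally concatenated with a standardized
age covariate), a 64-unit dense ReLU layer, dropout, and a 2-class softmax
head.  Forward and backward passes are written out explicitly so that the
gradient of a class logit with respect to the last convolutional feature
maps — the quantity Grad-CAM needs — is available without an autodiff
framework.

Conventions follow Keras defaults where the architecture is standard:
Glorot-uniform initialisation, inverted dropout, "same" or "valid" conv
padding, valid (floor) max-pooling, Adam with eps=1e-7.  All randomness
flows through explicitly passed ``numpy.random.Generator`` objects so two
runs from the same seed are bit-identical on a fixed BLAS.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv2d_geometry", "pooled_geometry", "PathCNNNet", "Adam"]

_DTYPE = np.float32


def conv2d_geometry(h: int, w: int, kernel: tuple[int, int], padding: str) -> tuple[int, int]:
    """Output height/width of a stride-1 conv layer."""
    kh, kw = kernel
    if padding == "same":
        return h, w
    if padding == "valid":
        return h - kh + 1, w - kw + 1
    raise ValueError(f"unknown padding mode {padding!r}")


def pooled_geometry(h: int, w: int, pool: tuple[int, int]) -> tuple[int, int]:
    """Output of a non-overlapping max-pool; trailing rows/cols that do not
    fill a window are dropped (floor semantics)."""
    return h // pool[0], w // pool[1]


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def _im2col(x: np.ndarray, kh: int, kw: int, padding: str) -> np.ndarray:
    """Return sliding patches of shape (N, Ho, Wo, kh, kw, C)."""
    if padding == "same":
        ph, pw = kh // 2, kw // 2
        x = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, Ho, Wo, C, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, padding: str):
    kh, kw, cin, cout = W.shape
    cols = _im2col(x, kh, kw, padding)  # (N, Ho, Wo, kh, kw, cin)
    n, ho, wo = cols.shape[:3]
    z = cols.reshape(n * ho * wo, kh * kw * cin) @ W.reshape(kh * kw * cin, cout)
    z = z.reshape(n, ho, wo, cout) + b
    return z, cols


def _conv_backward(dz: np.ndarray, cols: np.ndarray, x_shape: tuple, W: np.ndarray, padding: str):
    kh, kw, cin, cout = W.shape
    n, ho, wo = dz.shape[:3]
    dz_flat = dz.reshape(n * ho * wo, cout)
    dW = (cols.reshape(n * ho * wo, kh * kw * cin).T @ dz_flat).reshape(W.shape)
    db = dz_flat.sum(axis=0)
    dcols = (dz_flat @ W.reshape(kh * kw * cin, cout).T).reshape(n, ho, wo, kh, kw, cin)
    if padding == "same":
        ph, pw = kh // 2, kw // 2
        hp, wp = x_shape[1] + 2 * ph, x_shape[2] + 2 * pw
    else:
        ph = pw = 0
        hp, wp = x_shape[1], x_shape[2]
    dxp = np.zeros((n, hp, wp, cin), dtype=dz.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
    if padding == "same":
        return dW, db, dxp[:, ph : ph + x_shape[1], pw : pw + x_shape[2], :]
    return dW, db, dxp


def _maxpool_forward(x: np.ndarray, pool: tuple[int, int]):
    ph, pw = pool
    n, h, w, c = x.shape
    ho, wo = h // ph, w // pw
    xc = x[:, : ho * ph, : wo * pw, :]
    blocks = xc.reshape(n, ho, ph, wo, pw, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, ho, wo, ph * pw, c)
    idx = blocks.argmax(axis=3)
    out = np.take_along_axis(blocks, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, x_shape: tuple, pool: tuple[int, int]):
    ph, pw = pool
    n, h, w, c = x_shape
    ho, wo = h // ph, w // pw
    dblocks = np.zeros((n, ho, wo, ph * pw, c), dtype=dout.dtype)
    np.put_along_axis(dblocks, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : ho * ph, : wo * pw, :] = dblocks.reshape(n, ho, wo, ph, pw, c).transpose(0, 1, 3, 2, 4, 5).reshape(
        n, ho * ph, wo * pw, c
    )
    return dx


class PathCNNNet:
    """The fixed two-conv pathway-image classifier with explicit gradients.

    Parameters
    ----------
    image_shape : (rows, cols)
        Height and width of the input pathway image (single channel).
    conv_filters : pair of filter counts for the two conv layers.
    kernel, pool : spatial sizes of the conv kernels and the max-pool.
    padding : "same" (default) or "valid" for both conv layers.
    use_age : include a scalar age covariate, concatenated to the
        flattened pooled features before the dense layer.
    rng : generator used for weight initialisation.
    """

    def __init__(
        self,
        image_shape: tuple[int, int],
        conv_filters: tuple[int, int] = (32, 64),
        kernel: tuple[int, int] = (3, 3),
        pool: tuple[int, int] = (4, 2),
        dense_units: int = 64,
        dropout_conv: float = 0.25,
        dropout_dense: float = 0.50,
        padding: str = "same",
        use_age: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        h, w = image_shape
        c1, c2 = conv_filters
        h1, w1 = conv2d_geometry(h, w, kernel, padding)
        h2, w2 = conv2d_geometry(h1, w1, kernel, padding)
        hp, wp = pooled_geometry(h2, w2, pool)
        if min(h1, w1, h2, w2) < 1 or hp < 1 or wp < 1:
            raise ValueError(
                f"image shape {image_shape} too small for two {kernel} convolutions "
                f"({padding} padding) and a {pool} max-pool; need at least "
                f"{self._minimal_shape(kernel, pool, padding)}"
            )
        self.image_shape = (h, w)
        self.conv_shape = (h2, w2, c2)  # last-conv feature-map geometry
        self.pooled_shape = (hp, wp, c2)
        self.flat_dim = hp * wp * c2
        self.kernel, self.pool, self.padding = kernel, pool, padding
        self.dropout_conv, self.dropout_dense = dropout_conv, dropout_dense
        self.use_age = use_age
        self.age_mean: float = 0.0
        self.age_sd: float = 1.0
        dense_in = self.flat_dim + (1 if use_age else 0)
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        self.params = {
            "W1": _glorot_uniform(rng, (kh, kw, 1, c1), kh * kw * 1, kh * kw * c1),
            "b1": np.zeros(c1, dtype=_DTYPE),
            "W2": _glorot_uniform(rng, (kh, kw, c1, c2), kh * kw * c1, kh * kw * c2),
            "b2": np.zeros(c2, dtype=_DTYPE),
            "Wd": _glorot_uniform(rng, (dense_in, dense_units), dense_in, dense_units),
            "bd": np.zeros(dense_units, dtype=_DTYPE),
            "Wo": _glorot_uniform(rng, (dense_units, 2), dense_units, 2),
            "bo": np.zeros(2, dtype=_DTYPE),
        }

    @staticmethod
    def _minimal_shape(kernel, pool, padding):
        kh, kw = kernel
        if padding == "valid":
            return (2 * (kh - 1) + pool[0], 2 * (kw - 1) + pool[1])
        return (pool[0], pool[1])

    # ------------------------------------------------------------------ #

    def _standardize_age(self, age: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if not self.use_age:
            return None
        if age is None:
            raise ValueError("model was built with use_age=True but no age vector was given")
        return ((np.asarray(age, dtype=_DTYPE) - self.age_mean) / self.age_sd).astype(_DTYPE)

    def forward(
        self,
        x: np.ndarray,
        age: Optional[np.ndarray] = None,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> dict:
        """Full forward pass; returns a cache dict holding every intermediate."""
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        p = self.params
        z1, cols1 = _conv_forward(x, p["W1"], p["b1"], self.padding)
        a1 = np.maximum(z1, 0)
        z2, cols2 = _conv_forward(a1, p["W2"], p["b2"], self.padding)
        a2 = np.maximum(z2, 0)  # Grad-CAM feature maps A^k
        pooled, pidx = _maxpool_forward(a2, self.pool)
        if train and self.dropout_conv > 0:
            mask_c = (rng.random(pooled.shape) >= self.dropout_conv).astype(_DTYPE) / (1 - self.dropout_conv)
            pooled_d = pooled * mask_c
        else:
            mask_c, pooled_d = None, pooled
        flat = pooled_d.reshape(x.shape[0], -1)
        age_z = self._standardize_age(age)
        feat = np.concatenate([flat, age_z[:, None]], axis=1) if self.use_age else flat
        hz = feat @ p["Wd"] + p["bd"]
        ha = np.maximum(hz, 0)
        if train and self.dropout_dense > 0:
            mask_d = (rng.random(ha.shape) >= self.dropout_dense).astype(_DTYPE) / (1 - self.dropout_dense)
            ha_d = ha * mask_d
        else:
            mask_d, ha_d = None, ha
        logits = ha_d @ p["Wo"] + p["bo"]
        zmax = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - zmax)
        proba = e / e.sum(axis=1, keepdims=True)
        return {
            "x": x, "cols1": cols1, "z1": z1, "a1": a1, "cols2": cols2, "z2": z2,
            "a2": a2, "pooled": pooled, "pidx": pidx, "mask_c": mask_c, "flat": flat,
            "feat": feat, "hz": hz, "ha": ha, "mask_d": mask_d, "ha_d": ha_d,
            "logits": logits, "proba": proba,
        }

    def predict_proba(self, x: np.ndarray, age: Optional[np.ndarray] = None, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            a = None if age is None else age[i : i + batch_size]
            out.append(self.forward(x[i : i + batch_size], age=a)["proba"])
        return np.concatenate(out, axis=0)

    # ------------------------------------------------------------------ #

    def loss_and_grads(self, cache: dict, y: np.ndarray, sample_weight: np.ndarray) -> tuple[float, dict]:
        """Weighted softmax cross-entropy (mean of per-sample weighted losses)
        and gradients for every parameter."""
        n = len(y)
        proba = cache["proba"]
        w = np.asarray(sample_weight, dtype=_DTYPE)
        ce = -np.log(np.clip(proba[np.arange(n), y], 1e-12, None))
        loss = float(np.mean(w * ce))
        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (w / n)[:, None]
        grads: dict = {}
        p = self.params
        grads["Wo"] = cache["ha_d"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dha = dlogits @ p["Wo"].T
        if cache["mask_d"] is not None:
            dha = dha * cache["mask_d"]
        dhz = dha * (cache["hz"] > 0)
        grads["Wd"] = cache["feat"].T @ dhz
        grads["bd"] = dhz.sum(axis=0)
        dfeat = dhz @ p["Wd"].T
        dflat = dfeat[:, : self.flat_dim]
        dpooled = dflat.reshape((n,) + self.pooled_shape)
        if cache["mask_c"] is not None:
            dpooled = dpooled * cache["mask_c"]
        da2 = _maxpool_backward(dpooled, cache["pidx"], cache["a2"].shape, self.pool)
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"], grads["b2"], da1 = _conv_backward(dz2, cache["cols2"], cache["a1"].shape, p["W2"], self.padding)
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"], grads["b1"], _ = _conv_backward(dz1, cache["cols1"], cache["x"].shape, p["W1"], self.padding)
        return loss, grads

    # ------------------------------------------------------------------ #
    # Grad-CAM support

    def logit_from_conv(self, a2: np.ndarray, age: Optional[np.ndarray] = None) -> np.ndarray:
        """Class logits computed from given last-conv activations (eval mode).
        Used both by Grad-CAM finite-difference checks and as the head of the
        analytic gradient below."""
        pooled, _ = _maxpool_forward(a2, self.pool)
        flat = pooled.reshape(a2.shape[0], -1)
        age_z = self._standardize_age(age)
        feat = np.concatenate([flat, age_z[:, None]], axis=1) if self.use_age else flat
        ha = np.maximum(feat @ self.params["Wd"] + self.params["bd"], 0)
        return ha @ self.params["Wo"] + self.params["bo"]

    def conv_activations_and_grad(
        self, x: np.ndarray, class_idx: int, age: Optional[np.ndarray] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Last-conv activations A and d(logit_c)/dA, eval mode (no dropout).

        The backward pass from the logit down to A is recomputed in float64
        (mirroring :meth:`logit_from_conv` exactly) so the Grad-CAM weights
        are accurate even where individual gradients are tiny.

        Returns (a2, da2), both of shape (N, h, w, K).
        """
        cache = self.forward(x, age=age, train=False)
        a2 = cache["a2"]
        n = a2.shape[0]
        A = a2.astype(np.float64)
        pooled, pidx = _maxpool_forward(A, self.pool)
        flat = pooled.reshape(n, -1)
        if self.use_age:
            age_z = self._standardize_age(age).astype(np.float64)
            feat = np.concatenate([flat, age_z[:, None]], axis=1)
        else:
            feat = flat
        Wd = self.params["Wd"].astype(np.float64)
        hz = feat @ Wd + self.params["bd"].astype(np.float64)
        dha = np.tile(self.params["Wo"][:, class_idx].astype(np.float64)[None, :], (n, 1))
        dhz = dha * (hz > 0)
        dfeat = dhz @ Wd.T
        dpooled = dfeat[:, : self.flat_dim].reshape((n,) + self.pooled_shape)
        da2 = _maxpool_backward(dpooled, pidx, A.shape, self.pool)
        return a2, da2

    # ------------------------------------------------------------------ #

    def save_npz(self, path) -> None:
        """Persist architecture + weights as a plain NPZ checkpoint."""
        import json

        meta = dict(
            image_shape=list(self.image_shape),
            conv_filters=[int(self.params["W1"].shape[3]), int(self.params["W2"].shape[3])],
            kernel=list(self.kernel), pool=list(self.pool),
            dense_units=int(self.params["Wd"].shape[1]),
            dropout_conv=self.dropout_conv, dropout_dense=self.dropout_dense,
            padding=self.padding, use_age=self.use_age,
            age_mean=self.age_mean, age_sd=self.age_sd,
        )
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load_npz(cls, path) -> "PathCNNNet":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: z[k] for k in z.files if k != "__meta__"}
        net = cls(
            image_shape=tuple(meta["image_shape"]),
            conv_filters=tuple(meta["conv_filters"]),
            kernel=tuple(meta["kernel"]), pool=tuple(meta["pool"]),
            dense_units=meta["dense_units"],
            dropout_conv=meta["dropout_conv"], dropout_dense=meta["dropout_dense"],
            padding=meta["padding"], use_age=meta["use_age"],
            rng=np.random.default_rng(0),
        )
        net.params = params
        net.age_mean, net.age_sd = meta["age_mean"], meta["age_sd"]
        return net

    def get_weights(self) -> dict:
        return copy.deepcopy(self.params)

    def set_weights(self, params: dict) -> None:
        self.params = copy.deepcopy(params)

    def layer_summary(self) -> list[str]:
        h, w = self.image_shape
        c1 = self.params["W1"].shape[3]
        h2, w2, c2 = self.conv_shape
        hp, wp, _ = self.pooled_shape
        h1, w1 = conv2d_geometry(h, w, self.kernel, self.padding)
        rows = [
            f"input           {h}x{w}x1",
            f"conv 3x3 relu   {h1}x{w1}x{c1}",
            f"conv 3x3 relu   {h2}x{w2}x{c2}   <- Grad-CAM feature maps",
            f"maxpool {self.pool[0]}x{self.pool[1]}     {hp}x{wp}x{c2}",
            f"dropout p={self.dropout_conv}",
            f"flatten         {self.flat_dim}" + (" + age" if self.use_age else ""),
            f"dense relu      {self.params['Wd'].shape[1]}",
            f"dropout p={self.dropout_dense}",
            "dense softmax   2",
        ]
        return rows


class Adam:
    """Adam optimizer (Keras defaults: beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params: dict, learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(params[k].dtype)
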