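"""A compact U-Net implemented directly on numpy.

Encoder–decoder with skip connections: each encoder level applies two 3x3
convolutions (batch-norm + ReLU) and halves the resolution with 2x2 max
pooling; the decoder mirrors it with 2x2 transposed-convolution upsampling
and channel concatenation of the matching encoder feature map; a final 1x1
convolution produces per-pixel class logits.  Training minimizes softmax
cross-entropy with the Adam optimizer.

Everything — im2col convolutions, batch normalization, pooling, transposed
convolutions and their gradients — is explicit numpy, which keeps the model
deterministic under a fixed seed and fast enough for the desk-scale tile
sizes this package targets (tens of pixels, not the 512-px inputs of a
GPU deployment; the architecture is the same, only the scale differs).

Tensors are NCHW float32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["UNet", "AdamOptimizer", "softmax_cross_entropy"]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    """Base layer: holds parameters, their gradients, and a forward cache."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(_Layer):
    """Same-padding KxK convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.params["W"] = rng.normal(0.0, scale, size=(c_out, fan_in)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, c*k*k, h*w)
        return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self._cache = (cols, (n, c, h, w))
        y = np.einsum("fk,nkp->nfp", self.params["W"], cols, optimize=True)
        y += self.params["b"][None, :, None]
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.k, self.k // 2
        dy_flat = dy.reshape(n, self.c_out, h * w)
        self.grads["W"] = np.einsum("nfp,nkp->fk", dy_flat, cols, optimize=True)
        self.grads["b"] = dy_flat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.params["W"], dy_flat, optimize=True)
        dcols = dcols.reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for a in range(k):  # scatter-add the k*k shifted gradient planes
            for b in range(k):
                dxp[:, :, a : a + h, b : b + w] += dcols[:, :, a, b]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2D(_Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        # standard batch-norm gradient
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv_std[None, :, None, None] * (term1 - term2 - term3)


class ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(_Layer):
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class ConvTranspose2(_Layer):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / c_in)
        self.params["W"] = rng.normal(0.0, scale, size=(c_in, c_out, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("ncij,coab->noiajb", x, self.params["W"], optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w) + self.params["b"][None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        dyb = dy.reshape(n, self.c_out, h, 2, w, 2)
        self.grads["W"] = np.einsum("ncij,noiajb->coab", x, dyb, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        return np.einsum("noiajb,coab->ncij", dyb, self.params["W"], optimize=True)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, ignore_index: int = -1
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``labels`` holds class indices (N, H, W); pixels equal to
    ``ignore_index`` contribute neither loss nor gradient.
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    prob = ez / ez.sum(axis=1, keepdims=True)
    valid = labels != ignore_index
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    safe = np.where(valid, labels, 0)
    idx_n, idx_h, idx_w = np.meshgrid(
        np.arange(n), np.arange(h), np.arange(w), indexing="ij"
    )
    p_true = prob[idx_n, safe, idx_h, idx_w]
    loss = float(-(np.log(np.maximum(p_true, 1e-12)) * valid).sum() / n_valid)
    grad = prob.copy()
    one_hot_sub = np.zeros_like(grad)
    one_hot_sub[idx_n, safe, idx_h, idx_w] = 1.0
    grad -= one_hot_sub
    grad *= valid[:, None, :, :] / n_valid
    return loss, grad.astype(logits.dtype)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class AdamOptimizer:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[_Layer]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for lid, layer in enumerate(layers):
            if not layer.params:
                continue
            m = self._m.setdefault(lid, {k: np.zeros_like(v) for k, v in layer.params.items()})
            v = self._v.setdefault(lid, {k: np.zeros_like(p) for k, p in layer.params.items()})
            for key, p in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                mhat = m[key] / (1 - b1 ** self.t)
                vhat = v[key] / (1 - b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


@dataclass
class _DoubleConv:
    layers: list[_Layer]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy


class UNet:
    """U-Net for per-pixel tissue classification.

    Parameters
    ----------
    in_channels, n_classes
        Input image channels and number of output classes.
    depth
        Number of down/up-sampling levels; the input side length must be
        divisible by ``2 ** depth``.
    base_filters
        Channel count of the first encoder level; doubles per level.
    seed
        Seed for weight initialization.
    """

    def __init__(self, in_channels: int = 3, n_classes: int = 7, depth: int = 4,
                 base_filters: int = 16, seed: int = 0) -> None:
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.in_channels, self.n_classes = in_channels, n_classes
        self.depth, self.base_filters, self.seed = depth, base_filters, seed
        rng = np.random.default_rng(seed)

        def double_conv(cin: int, cout: int) -> _DoubleConv:
            return _DoubleConv([
                Conv2D(cin, cout, 3, rng), BatchNorm2D(cout), ReLU(),
                Conv2D(cout, cout, 3, rng), BatchNorm2D(cout), ReLU(),
            ])

        f = base_filters
        self.enc: list[_DoubleConv] = []
        self.pools: list[MaxPool2] = []
        cin = in_channels
        for d in range(depth):
            self.enc.append(double_conv(cin, f * 2 ** d))
            self.pools.append(MaxPool2())
            cin = f * 2 ** d
        self.bottleneck = double_conv(cin, f * 2 ** depth)
        self.ups: list[ConvTranspose2] = []
        self.dec: list[_DoubleConv] = []
        for d in reversed(range(depth)):
            ch = f * 2 ** d
            self.ups.append(ConvTranspose2(ch * 2, ch, rng))
            self.dec.append(double_conv(ch * 2, ch))  # after skip concat
        self.head = Conv2D(f, n_classes, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for blk in self.enc:
            out.extend(blk.layers)
        out.extend(self.pools)
        out.extend(self.bottleneck.layers)
        out.extend(self.ups)
        for blk in self.dec:
            out.extend(blk.layers)
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2] % (2 ** self.depth) or x.shape[3] % (2 ** self.depth):
            raise ValueError(
                f"input size {x.shape[2:]} not divisible by 2^depth = {2 ** self.depth}"
            )
        skips = []
        h = x.astype(np.float32)
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for blk, up in zip(reversed(self.dec), reversed(self.ups)):
            dy = blk.backward(dy)
            c = self._skip_channels[len(self.dec) - 1 - len(dskips)]
            dskip, dup = dy[:, :c], dy[:, c:]
            dskips.append(dskip)
            dy = up.backward(dup)
        dy = self.bottleneck.backward(dy)
        # dskips[0] is the gradient for the shallowest skip; encoder backward
        # runs deepest-first, so pair with the reversed list
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = blk.backward(dy + dskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, NCHW -> (N, K, H, W)."""
        logits = self.forward(x, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    # -- (de)serialization -------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, lyr in enumerate(self.layers()):
            for k, v in lyr.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(lyr, BatchNorm2D):
                state[f"{i}.running_mean"] = lyr.running_mean.copy()
                state[f"{i}.running_var"] = lyr.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, lyr in enumerate(self.layers()):
            for k in lyr.params:
                lyr.params[k] = state[f"{i}.{k}"].copy()
            if isinstance(lyr, BatchNorm2D):
                lyr.running_mean = state[f"{i}.running_mean"].copy()
                lyr.running_var = state[f"{i}.running_var"].copy()

    def save(self, path: str, sidecar: dict | None = None) -> None:
        # deterministic npz: fixed zip timestamps so identical weights give
        # byte-identical checkpoints (np.savez stamps the current time)
        import io
        import zipfile

        npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        with zipfile.ZipFile(npz, "w", zipfile.ZIP_STORED) as zf:
            for name, arr in self.get_state().items():
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.asarray(arr))
                info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())
        meta = {
            "in_channels": self.in_channels, "n_classes": self.n_classes,
            "depth": self.depth, "base_filters": self.base_filters,
            "seed": self.seed,
        }
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "UNet":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        net = cls(
            in_channels=meta["in_channels"], n_classes=meta["n_classes"],
            depth=meta["depth"], base_filters=meta["base_filters"],
            seed=meta.get("seed", 0),
        )
        npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        import os

        if not os.path.exists(npz):
            npz = str(path)
        with np.load(npz) as data:
            net.set_state({k: data[k] for k in data.files})
        return net
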