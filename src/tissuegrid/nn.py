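"""A small NumPy neural-net engine: layers with explicit forward/backward
passes, an Adam optimizer, and a Sequential container that can expose the
activations and gradients of any named layer (used for Grad-CAM).

Conventions: images are NCHW float arrays, feature vectors are (B, n).
Every layer owns its parameters in ``self.params`` and accumulates
gradients of the same shapes in ``self.grads`` during ``backward``.
All initialization is small-uniform ±1/sqrt(fan_in) from a caller-supplied
``numpy.random.Generator`` so construction is fully deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Dense",
    "BilinearLayerNN",
    "AttentionGateNN",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_with_logits",
]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int,
                  dtype=np.float32) -> np.ndarray:
    s = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-s, s, size=shape).astype(dtype)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' padding for odd kernels, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.params = {
            "W": _uniform_init(rng, (fan_in, out_ch), fan_in, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.zero_grad()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, H, W, C, k, k) -> (B*H*W, C*k*k)
        B, C, H, W = win.shape[:4]
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k), (B, H, W)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, (B, H, W) = self._im2col(x)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        B, _, H, W = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(B * H * W, self.out_ch)
        self.grads["W"] += cols.T @ gmat
        self.grads["b"] += gmat.sum(axis=0)
        gcols = gmat @ self.params["W"].T
        k, p = self.kernel, self.pad
        gcols = gcols.reshape(B, H, W, self.in_ch, k, k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((B, self.in_ch, H + 2 * p, W + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + H, j : j + W] += gcols[:, :, :, :, i, j]
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {H}x{W}")
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        self._argmax = r.argmax(axis=-1)
        self._in_shape = (B, C, H, W)
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        flat = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(flat, self._argmax[..., None], g[..., None], axis=-1)
        flat = flat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(B, C, H, W)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.params = {
            "W": _uniform_init(rng, (n_in, n_out), n_in, dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ g
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"].T


class BilinearLayerNN(Layer):
    """Differentiable bank of m bilinear nodes over an n-dim input.

    Output j of a sample x is  b_j + w_j'x + ||F_j x||^2  with F_j the j-th
    k x n factor matrix.  ``shared_f=True`` uses one F for all nodes (a
    memory-saving variant); the default keeps a full per-node F.
    """

    def __init__(self, n_in: int, n_out: int, n_factors: int,
                 rng: np.random.Generator, shared_f: bool = False,
                 dtype=np.float32):
        super().__init__()
        self.n_in, self.n_out, self.n_factors = n_in, n_out, n_factors
        self.shared_f = shared_f
        f_shape = (1 if shared_f else n_out, n_factors, n_in)
        self.params = {
            "W": _uniform_init(rng, (n_out, n_in), n_in, dtype),
            "b": _uniform_init(rng, (n_out,), n_in, dtype),
            "F": _uniform_init(rng, f_shape, n_in, dtype),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        F = self.params["F"]
        Fx = np.einsum("mkn,bn->bmk", F, x)  # (B,1,k) when shared, broadcasts
        y = self.params["b"] + x @ self.params["W"].T + (Fx ** 2).sum(axis=2)
        self._cache = (x, Fx)
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, Fx = self._cache
        F = self.params["F"]
        self.grads["b"] += g.sum(axis=0)
        self.grads["W"] += g.T @ x
        if self.shared_f:
            gq = g.sum(axis=1)[:, None]  # (B,1) — all nodes share the quad term
            self.grads["F"] += 2.0 * np.einsum("bm,bmk,bn->mkn", gq, Fx, x)
            FtFx = np.einsum("mkn,bmk->bn", F, Fx)
            gx = g @ self.params["W"] + 2.0 * gq[:, 0, None] * FtFx
        else:
            self.grads["F"] += 2.0 * np.einsum("bm,bmk,bn->mkn", g, Fx, x)
            FtFx = np.einsum("mkn,bmk->bmn", F, Fx)
            gx = g @ self.params["W"] + 2.0 * np.einsum("bm,bmn->bn", g, FtFx)
        return gx


class AttentionGateNN(Layer):
    """Differentiable soft-attention gate r = a ⊙ f, a = softmax(w ⊙ f)."""

    def __init__(self, n: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.params = {"w": _uniform_init(rng, (n,), n, dtype)}
        self.zero_grad()

    def forward(self, f: np.ndarray, train: bool = False) -> np.ndarray:
        w = self.params["w"]
        e = f * w
        z = np.exp(e - e.max(axis=1, keepdims=True))
        a = z / z.sum(axis=1, keepdims=True)
        self._cache = (f, a)
        return a * f

    def backward(self, g: np.ndarray) -> np.ndarray:
        f, a = self._cache
        w = self.params["w"]
        t = g * f                                   # dL/da
        ge = a * (t - (a * t).sum(axis=1, keepdims=True))  # softmax Jacobian^T
        self.grads["w"] += (f * ge).sum(axis=0)
        return g * a + w * ge


class Sequential:
    """Ordered named layers with full backprop and per-layer capture."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers
        self._names = [n for n, _ in layers]
        if len(set(self._names)) != len(self._names):
            raise ValueError("layer names must be unique")

    def __getitem__(self, name: str) -> Layer:
        return dict(self.layers)[name]

    def forward(self, x: np.ndarray, train: bool = False,
                capture: str | None = None):
        """Run the net; if ``capture`` names a layer, also return that
        layer's output (its activation)."""
        captured = None
        for name, layer in self.layers:
            x = layer.forward(x, train=train)
            if name == capture:
                captured = x
        return (x, captured) if capture is not None else x

    def backward(self, g: np.ndarray, capture: str | None = None):
        """Backpropagate ``g`` (gradient at the final output).  If
        ``capture`` names a layer, also return the gradient with respect to
        that layer's *output*."""
        captured = None
        for name, layer in reversed(self.layers):
            if name == capture:
                captured = g
            g = layer.backward(g)
        return (g, captured) if capture is not None else g

    def zero_grad(self) -> None:
        for _, layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        for name, layer in self.layers:
            for key in layer.params:
                yield f"{name}.{key}", layer.params[key], layer.grads[key]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.copy() for k, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for key in layer.params:
                full = f"{name}.{key}"
                if full not in state:
                    raise KeyError(f"missing parameter {full} in checkpoint")
                if state[full].shape != layer.params[key].shape:
                    raise ValueError(
                        f"shape mismatch for {full}: checkpoint "
                        f"{state[full].shape} vs model {layer.params[key].shape}"
                    )
                layer.params[key] = state[full].copy()


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, model: Sequential, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p) for k, p, _ in model.parameters()}
        self._v = {k: np.zeros_like(p) for k, p, _ in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p, g in self.model.parameters():
            if self.weight_decay:
                g = g + self.weight_decay * p
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * g
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    with np.errstate(invalid="ignore", over="ignore"):
        # non-finite logits propagate to a non-finite loss, which the
        # training loop detects and reports
        zmax = logits.max(axis=1, keepdims=True)
        lse = zmax[:, 0] + np.log(np.exp(logits - zmax).sum(axis=1))
        loss = float(np.mean(lse - logits[np.arange(B), labels]))
        grad = softmax(logits)
    grad[np.arange(B), labels] -= 1.0
    return loss, grad / B
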