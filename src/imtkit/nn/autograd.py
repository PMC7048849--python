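"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the translation and segmentation networks
need: strided convolution and transposed convolution (im2col based), batch
normalization, pooling, pointwise activations, channel concatenation,
dropout, and the scalar loss reductions.  Tensors form a DAG; ``backward``
runs a topological sweep accumulating gradients into ``Tensor.grad``.

All tensors are ``float64`` NCHW unless noted.  No in-place graph mutation;
randomness (dropout) is injected through explicit ``numpy.random.Generator``
instances so training runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "conv_transpose2d",
    "batch_norm2d",
    "max_pool2d",
    "leaky_relu",
    "relu",
    "tanh",
    "sigmoid",
    "dropout",
    "concat",
    "add",
    "crop_like",
    "affine_sum",
    "l1_loss",
    "bce_loss",
    "softmax_cross_entropy",
]


class Tensor:
    """A node in the autodiff graph wrapping a NumPy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor; ``seed`` defaults to ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); w has shape (F, C, k, k)."""
    f, c, k, _ = w.data.shape
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wm = w.data.reshape(f, c * k * k)
    out = np.einsum("fk,nkl->nfl", wm, cols).reshape(x.data.shape[0], f, ho, wo)
    out += b.data.reshape(1, f, 1, 1)

    def backward(g):
        gf = g.reshape(g.shape[0], f, ho * wo)
        if b.requires_grad:
            b._accumulate(gf.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nfl,nkl->fk", gf, cols)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad or x._parents:
            gcols = np.einsum("fk,nfl->nkl", wm, gf)
            x._accumulate(_col2im(gcols, x.data.shape, k, stride, pad))

    return _make(out, (x, w, b), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; w has shape (C_in, F, k, k).

    Output spatial size is ``(H-1)*stride - 2*pad + k`` (the usual inverse of
    the stride-``stride`` convolution used in the encoder).
    """
    n, c, h, wd = x.data.shape
    _, f, k, _ = w.data.shape
    ho = (h - 1) * stride - 2 * pad + k
    wo = (wd - 1) * stride - 2 * pad + k
    wm = w.data.reshape(c, f * k * k)
    xf = x.data.reshape(n, c, h * wd)
    cols = np.einsum("ck,ncl->nkl", wm, xf)
    out = _col2im(cols, (n, f, ho, wo), k, stride, pad)
    out += b.data.reshape(1, f, 1, 1)

    def backward(g):
        gcols, _, _ = _im2col(g, k, stride, pad)  # (n, f*k*k, h*wd)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("ncl,nkl->ck", xf, gcols)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad or x._parents:
            gx = np.einsum("ck,nkl->ncl", wm, gcols).reshape(n, c, h, wd)
            x._accumulate(gx)

    return _make(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# Normalization / pooling
# ---------------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    With batch size 1 the statistics are per-instance, the regime the
    translation network trains in.  ``running_*`` arrays are updated in place
    in training mode and used verbatim in eval mode.
    """
    c = x.data.shape[1]
    if train:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gv = gamma.data.reshape(1, c, 1, 1)
            if train:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gxhat = g * gv
                gx = (
                    gxhat
                    - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                ) * inv.reshape(1, c, 1, 1)
                del m
            else:
                gx = g * gv * inv.reshape(1, c, 1, 1)
            x._accumulate(gx)

    return _make(out, (x, gamma, beta), backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k max pooling (spatial dims must divide by k)."""
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]

    def backward(g):
        if x.requires_grad or x._parents:
            gx = mask * g[:, :, :, None, :, None]
            # split ties evenly so the adjoint stays exact
            counts = mask.sum(axis=(3, 5), keepdims=True)
            x._accumulate((gx / counts).reshape(n, c, h, w))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Pointwise ops
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = np.where(x.data > 0, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(np.where(x.data > 0, g, slope * g))

    return _make(out, (x,), backward)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(g * (1.0 - out * out))

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, active: bool) -> Tensor:
    """Inverted dropout; identity when inactive or p == 0."""
    if not active or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = x.data * mask

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(g * mask)

    return _make(out, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel (axis 1) concatenation of two NCHW tensors."""
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g[:, :ca])
        if b.requires_grad or b._parents:
            b._accumulate(g[:, ca:])

    return _make(out, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g)
        if b.requires_grad or b._parents:
            b._accumulate(g)

    return _make(out, (a, b), backward)


def crop_like(x: Tensor, ref: Tensor) -> Tensor:
    """Center-crop x spatially to ref's H×W (used by segmenter skip fusion)."""
    h, w = ref.data.shape[2], ref.data.shape[3]
    hx, wx = x.data.shape[2], x.data.shape[3]
    if (hx, wx) == (h, w):
        return x
    i0, j0 = (hx - h) // 2, (wx - w) // 2
    out = x.data[:, :, i0 : i0 + h, j0 : j0 + w]

    def backward(g):
        if x.requires_grad or x._parents:
            gx = np.zeros_like(x.data)
            gx[:, :, i0 : i0 + h, j0 : j0 + w] = g
            x._accumulate(gx)

    return _make(out, (x,), backward)


def affine_sum(tensors: list[Tensor], coeffs: list[float]) -> Tensor:
    """Scalar linear combination sum_i coeffs[i] * tensors[i] (all scalars)."""
    out = sum(c * t.data for t, c in zip(tensors, coeffs))

    def backward(g):
        for t, c in zip(tensors, coeffs):
            if t.requires_grad or t._parents:
                t._accumulate(c * g)

    return _make(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def l1_loss(yhat: Tensor, y: Tensor) -> Tensor:
    """Mean absolute deviation between two tensors (scalar output)."""
    diff = yhat.data - y.data
    out = np.abs(diff).mean()

    def backward(g):
        gd = g * np.sign(diff) / diff.size
        if yhat.requires_grad or yhat._parents:
            yhat._accumulate(gd)
        if y.requires_grad or y._parents:
            y._accumulate(-gd)

    return _make(out, (yhat, y), backward)


def bce_loss(scores: Tensor, target: float, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy of a sigmoid score map against a constant label.

    Scores are clamped to [eps, 1-eps] before the logarithms so the loss stays
    finite even for a saturated discriminator.
    """
    s = np.clip(scores.data, eps, 1.0 - eps)
    out = -(target * np.log(s) + (1.0 - target) * np.log(1.0 - s)).mean()

    def backward(g):
        if scores.requires_grad or scores._parents:
            inside = (scores.data > eps) & (scores.data < 1.0 - eps)
            gs = g * (-(target / s) + (1.0 - target) / (1.0 - s)) / s.size
            scores._accumulate(np.where(inside, gs, 0.0))

    return _make(out, (scores,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          pixel_weights: np.ndarray | None = None) -> Tensor:
    """Per-pixel softmax cross-entropy, weighted-averaged over all pixels.

    logits: (N, K, H, W); labels: (N, H, W) integer class indices;
    pixel_weights: optional (N, H, W) non-negative weights (normalized by
    their sum).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n, k, h, w = probs.shape
    idx = (
        np.repeat(np.arange(n), h * w),
        labels.reshape(-1),
        np.tile(np.repeat(np.arange(h), w), n),
        np.tile(np.arange(w), n * h),
    )
    picked = probs[idx].reshape(n, h, w)
    ce = -np.log(np.clip(picked, 1e-12, None))
    if pixel_weights is None:
        wsum = float(n * h * w)
        wmap = None
        out = ce.mean()
    else:
        wmap = np.asarray(pixel_weights, dtype=np.float64)
        wsum = float(wmap.sum())
        out = (ce * wmap).sum() / wsum

    def backward(g):
        if logits.requires_grad or logits._parents:
            gx = probs.copy()
            onehot = np.zeros_like(probs)
            onehot[idx] = 1.0
            gx -= onehot
            if wmap is not None:
                gx *= wmap[:, None, :, :]
            logits._accumulate(g * gx / wsum)

    return _make(out, (logits,), backward)
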