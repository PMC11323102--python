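"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation networks in this package are small encoder--decoder CNNs
trained on a CPU, so instead of depending on a deep-learning framework the
package carries its own tape-based autodiff core.  Arrays are float32 and
image tensors use the NHWC layout (batch, height, width, channels).

Every primitive stores a closure that maps the output gradient onto its
parents; :meth:`Tensor.backward` runs the closures in reverse topological
order.  All primitives are covered by central-difference gradient checks in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]

_DTYPE = np.float32


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GradMode.enabled
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- bookkeeping ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for CNN forward passes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        out._backward = backward
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    # -- nonlinearities ------------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g * (self.data > 0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g * e)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g / self.data)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the interior (hard clamp)."""
        out = Tensor(np.clip(self.data, lo, hi), requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g * ((self.data >= lo) & (self.data <= hi)))

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(_DTYPE))
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accumulate(np.broadcast_to(g, self.shape).astype(_DTYPE))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int | tuple[int, ...], keepdims: bool = False) -> "Tensor":
        """Max reduction; the gradient flows to the first arg-max entry only."""
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        m = self.data.max(axis=axes, keepdims=True)
        onehot = (self.data == m).astype(_DTYPE)
        # split ties evenly so the gradient check stays symmetric
        onehot /= onehot.sum(axis=axes, keepdims=True)
        val = m if keepdims else np.squeeze(m, axis=axes)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(onehot * g)

        out._backward = backward
        return out

    # -- shape manipulation --------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _parents=(self,))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = backward
        return out

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the two spatial axes of an NHWC tensor."""
        if pad == 0:
            return self
        width = ((0, 0), (pad, pad), (pad, pad), (0, 0))
        out = Tensor(np.pad(self.data, width), requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            self._accumulate(g[:, pad:-pad, pad:-pad, :])

        out._backward = backward
        return out

    # -- linear algebra ------------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- convolution and resampling primitives -------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None, stride: int = 1,
               pad: int | None = None) -> "Tensor":
        """2-D convolution, NHWC input, HWIO weight, 'same'-style zero padding.

        Implemented as a sum of strided slices times per-offset weight matrices
        so that the heavy lifting is BLAS matmuls.
        """
        k = weight.shape[0]
        if pad is None:
            pad = (k - 1) // 2
        xp = self.pad2d(pad)
        n, hp, wp, ci = xp.shape
        co = weight.shape[3]
        ho = (hp - k) // stride + 1
        wo = (wp - k) // stride + 1
        # im2col: one big GEMM beats k*k small ones on a single core; the
        # column buffer is filled by k*k regular strided copies (fast path)
        cols6 = np.empty((n, ho, wo, k, k, ci), dtype=_DTYPE)
        for dy in range(k):
            for dx in range(k):
                cols6[:, :, :, dy, dx, :] = xp.data[
                    :, dy : dy + (ho - 1) * stride + 1 : stride,
                    dx : dx + (wo - 1) * stride + 1 : stride]
        cols = cols6.reshape(n * ho * wo, k * k * ci)
        wmat = weight.data.reshape(k * k * ci, co)
        out_data = (cols @ wmat).reshape(n, ho, wo, co)
        if bias is not None:
            out_data += bias.data
        parents = (xp, weight) + ((bias,) if bias is not None else ())
        out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents),
                     _parents=parents)

        def backward(g):
            gflat = g.reshape(-1, co)
            if weight.requires_grad:
                weight._accumulate((cols.T @ gflat).reshape(weight.shape))
            if xp.requires_grad:
                gcols = (gflat @ wmat.T).reshape(n, ho, wo, k, k, ci)
                gx = np.zeros_like(xp.data)
                for dy in range(k):
                    for dx in range(k):
                        gx[:, dy : dy + (ho - 1) * stride + 1 : stride,
                           dx : dx + (wo - 1) * stride + 1 : stride] += gcols[:, :, :, dy, dx]
                xp._accumulate(gx)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1, 2)))

        out._backward = backward
        return out

    def depthwise_conv2d(self, weight: "Tensor", stride: int = 1) -> "Tensor":
        """Depth-wise 2-D convolution; weight is (k, k, c), 'same' padding."""
        k = weight.shape[0]
        pad = (k - 1) // 2
        xp = self.pad2d(pad)
        n, hp, wp, c = xp.shape
        ho = (hp - k) // stride + 1
        wo = (wp - k) // stride + 1
        xpd, wd = xp.data, weight.data
        out_data = np.zeros((n, ho, wo, c), dtype=_DTYPE)
        slices = []
        for dy in range(k):
            for dx in range(k):
                sl = (
                    slice(None),
                    slice(dy, dy + (ho - 1) * stride + 1, stride),
                    slice(dx, dx + (wo - 1) * stride + 1, stride),
                    slice(None),
                )
                slices.append(sl)
                out_data += xpd[sl] * wd[dy, dx]
        out = Tensor(out_data, requires_grad=xp.requires_grad or weight.requires_grad,
                     _parents=(xp, weight))

        def backward(g):
            if xp.requires_grad:
                gx = np.zeros_like(xpd)
            for idx, (dy, dx) in enumerate((a, b) for a in range(k) for b in range(k)):
                sl = slices[idx]
                if weight.requires_grad:
                    if weight.grad is None:
                        weight.grad = np.zeros_like(wd)
                    weight.grad[dy, dx] += (xpd[sl] * g).sum(axis=(0, 1, 2))
                if xp.requires_grad:
                    gx[sl] += g * wd[dy, dx]
            if xp.requires_grad:
                xp._accumulate(gx)

        out._backward = backward
        return out

    def batchnorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5
                  ) -> tuple["Tensor", np.ndarray, np.ndarray]:
        """Fused batch normalisation over all axes but the last.

        Returns (normalised tensor, batch mean, batch var); the fused backward
        avoids the long chain of elementwise nodes a composed version builds.
        """
        axes = tuple(range(self.ndim - 1))
        m = int(np.prod([self.shape[a] for a in axes]))
        mu = self.data.mean(axis=axes)
        var = self.data.var(axis=axes)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = Tensor(
            xhat * gamma.data + beta.data,
            requires_grad=self.requires_grad or gamma.requires_grad or beta.requires_grad,
            _parents=(self, gamma, beta),
        )

        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if self.requires_grad:
                gxhat = g * gamma.data
                term = gxhat - gxhat.mean(axis=axes) - xhat * (gxhat * xhat).mean(axis=axes)
                self._accumulate(term * inv)

        out._backward = backward
        return out, mu, var

    def upsample2x_nearest(self) -> "Tensor":
        out_data = self.data.repeat(2, axis=1).repeat(2, axis=2)
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))
        n, h, w, c = self.shape

        def backward(g):
            self._accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

        out._backward = backward
        return out

    def upsample2x_bilinear(self) -> "Tensor":
        """Factor-2 bilinear upsampling (half-pixel centres), separable gathers."""
        n, h, w, c = self.shape
        i0, i1, wi = _bilinear_indices(h)
        j0, j1, wj = _bilinear_indices(w)
        x = self.data
        rows = x[:, i0] * (1 - wi)[None, :, None, None] + x[:, i1] * wi[None, :, None, None]
        out_data = (
            rows[:, :, j0] * (1 - wj)[None, None, :, None]
            + rows[:, :, j1] * wj[None, None, :, None]
        ).astype(_DTYPE)
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def backward(g):
            grows = np.zeros((n, 2 * h, w, c), dtype=_DTYPE)
            np.add.at(grows, (slice(None), slice(None), j0), g * (1 - wj)[None, None, :, None])
            np.add.at(grows, (slice(None), slice(None), j1), g * wj[None, None, :, None])
            gx = np.zeros_like(x)
            np.add.at(gx, (slice(None), i0), grows * (1 - wi)[None, :, None, None])
            np.add.at(gx, (slice(None), i1), grows * wi[None, :, None, None])
            self._accumulate(gx)

        out._backward = backward
        return out


def _bilinear_indices(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = (np.arange(2 * size, dtype=np.float64) + 0.5) / 2.0 - 0.5
    lo = np.clip(np.floor(coords), 0, size - 1).astype(np.intp)
    hi = np.clip(lo + 1, 0, size - 1)
    frac = np.clip(coords - lo, 0.0, 1.0).astype(_DTYPE)
    return lo, hi, frac


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax built from primitives (max is detached)."""
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    out = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != (axis % out.ndim)))
    return out
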