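"""Neural-network building blocks (modules, layers, optimizers).

Thin layer classes over :mod:`ccgan.autodiff`, in the spirit of a miniature
torch.nn: a :class:`Module` owns named parameters and submodules, layers are
callables from Tensor to Tensor, and optimizers update parameters in place.
Initialisation is fully determined by the ``numpy.random.Generator`` handed to
each constructor, so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter traversal and train/eval mode switching."""

    _buffers: tuple[str, ...] = ()  # non-trainable state (e.g. BN running stats)

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            for name in m._buffers:
                state.append(getattr(m, name).copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = [(m, name) for m in self.modules() for name in m._buffers]
        if len(params) + len(buffers) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model has "
                f"{len(params)} parameters + {len(buffers)} buffers"
            )
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=_DTYPE).reshape(p.shape)
        for (m, name), arr in zip(buffers, state[len(params):]):
            setattr(m, name, np.asarray(arr, dtype=_DTYPE).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(_he_init(rng, (kernel, kernel, in_ch, out_ch),
                                         kernel * kernel * in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride)


class SeparableConv2d(Module):
    """Depth-wise 3x3 followed by a point-wise 1x1 projection."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.depthwise = Parameter(_he_init(rng, (kernel, kernel, in_ch), kernel * kernel))
        self.pointwise = Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(x.depthwise_conv2d(self.depthwise))


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running statistics."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=_DTYPE))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = x.batchnorm(self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            return out
        xhat = (x - Tensor(self.running_mean)) * Tensor(
            1.0 / np.sqrt(self.running_var + self.eps)
        )
        return xhat * self.gamma + self.beta


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Dropout(Module):
    """Inverted dropout; the noise source doubles as the GAN's latent noise n."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(_DTYPE) / (1.0 - self.p)
        return x * Tensor(keep)


class ConvBlock(Module):
    """conv -> BN -> ReLU, the repeating unit of every network here."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


# ---------------------------------------------------------------------------
# Optimizers


class Optimizer:
    def __init__(self, params: list[Parameter], weight_decay: float = 0.0):
        self.params = list(params)
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _grad(self, p: Parameter) -> np.ndarray:
        g = p.grad
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g

    def step(self) -> None:
        raise NotImplementedError


class Adadelta(Optimizer):
    """Adadelta with accumulated squared gradients and updates (rho, eps as usual)."""

    def __init__(self, params, lr: float = 0.001, rho: float = 0.95, eps: float = 1e-6,
                 weight_decay: float = 1e-4):
        super().__init__(params, weight_decay)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq_grad = [np.zeros_like(p.data) for p in self.params]
        self.sq_delta = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._grad(p)
            self.sq_grad[i] = self.rho * self.sq_grad[i] + (1 - self.rho) * g * g
            delta = np.sqrt((self.sq_delta[i] + self.eps) / (self.sq_grad[i] + self.eps)) * g
            self.sq_delta[i] = self.rho * self.sq_delta[i] + (1 - self.rho) * delta * delta
            p.data -= self.lr * delta


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, weight_decay)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._grad(p)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
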