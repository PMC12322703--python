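"""Layer / container abstractions over the autograd tensors."""
from __future__ import annotations

import contextlib
import math

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d

_INIT_RNG = np.random.default_rng(0)


@contextlib.contextmanager
def init_seed(seed: int):
    """Make parameter initialisation deterministic for the enclosed block."""
    global _INIT_RNG
    prev = _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _INIT_RNG = prev


def Parameter(data) -> Tensor:
    t = Tensor(data, requires_grad=True)
    return t


class Module:
    def __init__(self):
        self._parameters: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True
        self._fwd_hooks: list = []

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_parameters", {})[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        for h in self._fwd_hooks:
            h(self, args, out)
        return out

    def register_forward_hook(self, fn):
        self._fwd_hooks.append(fn)
        return fn

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._parameters.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({"buf::" + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for n, p in params.items():
            p.data = np.asarray(d[n], dtype=np.float32).reshape(p.data.shape)
        # buffers are stored by reference in modules; update in place
        for (n, b) in self.named_buffers():
            key = "buf::" + n
            if key in d:
                b[...] = d[key]

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel, stride=1, padding=0,
                 dilation=1, groups: int = 1, bias: bool = False):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.cin, self.cout = cin, cout
        self.kernel = (kh, kw)
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = cin // groups * kh * kw
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(_INIT_RNG.normal(0.0, std, (cout, cin // groups, kh, kw)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        y = conv2d(x, self.weight, self.stride, self.padding, self.dilation, self.groups)
        if self.bias is not None:
            y = y + self.bias.reshape(1, self.cout, 1, 1)
        return y


class Conv1d(Module):
    """1-D convolution realised as a (1, k) 2-D convolution."""

    def __init__(self, cin: int, cout: int, kernel: int, padding: int = 0, bias: bool = False):
        super().__init__()
        self.conv = Conv2d(cin, cout, (1, kernel), padding=(0, padding), bias=bias)

    def forward(self, x):
        # x: (N, C, L)
        n, c, l = x.shape
        y = self.conv(x.reshape(n, c, 1, l))
        return y.reshape(n, self.conv.cout, l)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor):
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            xhat = xc * (v + self.eps).pow(-0.5)
        else:
            mu = self.running_mean.reshape(1, self.c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, self.c, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.weight.reshape(1, self.c, 1, 1) + self.bias.reshape(1, self.c, 1, 1)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class ConvBNAct(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, padding=1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride=stride, padding=padding)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.relu() if self.act else y


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class Adam:
    """Adam optimiser with optional global gradient-norm clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, clip_norm: float | None = None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay, self.clip_norm = weight_decay, clip_norm
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        if self.clip_norm is not None:
            clip_grad_norm(self.params, self.clip_norm)
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self._t
        bc2 = 1 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    """Stochastic gradient descent with classical momentum, weight decay and
    optional global gradient-norm clipping."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0, clip_norm: float | None = None):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        if self.clip_norm is not None:
            clip_grad_norm(self.params, self.clip_norm)
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
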