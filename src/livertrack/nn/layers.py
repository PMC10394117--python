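"""Network building blocks on top of the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "Conv3d", "BatchNorm2d", "Linear",
    "ReLU", "LeakyReLU", "GraphConv",
]


class Module:
    """Base class: parameter traversal, train/eval mode, state dict."""

    def __init__(self):
        self._params = {}
        self._modules = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def buffers(self, prefix=""):
        for k, v in getattr(self, "_buffers", {}).items():
            yield prefix + k, v
        for k, m in self._modules.items():
            yield from m.buffers(prefix + k + ".")

    def register_buffer(self, name, value):
        self.__dict__.setdefault("_buffers", {})[name] = value
        object.__setattr__(self, name, value)

    def train(self, mode=True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({"buf:" + k: v.copy() for k, v in self.buffers()})
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            p.data[...] = state[k]
        for k, v in self.buffers():
            v[...] = state["buf:" + k]

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            setattr(self, f"l{i}", l)

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x


def _he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        w = np.zeros((cout, cin, k, k)) if zero_init else _he_normal(
            rng, (cout, cin, k, k), cin * k * k)
        self.w = ad.parameter(w)
        self.b = ad.parameter(np.zeros(cout))

    def forward(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Conv3d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        w = np.zeros((cout, cin, k, k, k)) if zero_init else _he_normal(
            rng, (cout, cin, k, k, k), cin * k ** 3)
        self.w = ad.parameter(w)
        self.b = ad.parameter(np.zeros(cout))

    def forward(self, x):
        return ad.conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = ad.parameter(np.ones(c))
        self.beta = ad.parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c))
        self.register_buffer("running_var", np.ones(c))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return ad.batchnorm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training,
                            self.momentum, self.eps)


class Linear(Module):
    def __init__(self, fin, fout, rng=None, zero_init=False, scale=1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = np.zeros((fin, fout)) if zero_init else (
            scale * rng.normal(0.0, np.sqrt(1.0 / fin), size=(fin, fout)))
        self.w = ad.parameter(w)
        self.b = ad.parameter(np.zeros(fout))

    def forward(self, x):
        return (x @ self.w) + self.b


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class GraphConv(Module):
    """Graph convolution over a fixed mesh: separate self and neighbor-mean
    transforms,  y_p = x_p W_self + mean_{q in N(p)} x_q W_nbr + b.
    """

    def __init__(self, fin, fout, neighbor_mean: np.ndarray, rng=None,
                 zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.M = ad.constant(neighbor_mean)
        if zero_init:
            self.w_self = ad.parameter(np.zeros((fin, fout)))
            self.w_nbr = ad.parameter(np.zeros((fin, fout)))
        else:
            self.w_self = ad.parameter(_he_normal(rng, (fin, fout), fin))
            self.w_nbr = ad.parameter(_he_normal(rng, (fin, fout), fin))
        self.b = ad.parameter(np.zeros(fout))

    def forward(self, x):
        return (x @ self.w_self) + ((self.M @ x) @ self.w_nbr) + self.b
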