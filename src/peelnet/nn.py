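"""Minimal neural-network layer library on top of :mod:`peelnet.autodiff`.

Layers mirror the conventions of mainstream detector codebases: Conv-BN-SiLU
blocks, batch normalization with running statistics, He initialization, Adam.
Parameter initialization draws from a module-level generator so that a single
`seed_all(seed)` call makes model construction reproducible.
"""

from __future__ import annotations

import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed parameter initialization (model construction order is fixed)."""
    global _rng
    _rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # buffers (running BN stats, fixed kernels) live in _buffers dicts
    def named_buffers(self, prefix: str = ""):
        for name, v in getattr(self, "_buffers", {}).items():
            yield prefix + name, v
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self):
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: v.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        for k, v in self.named_parameters():
            v.data[...] = d[k]
        for k, v in self.named_buffers():
            v[...] = d[k]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = c_in // groups * k * k
        self.weight = Parameter(_rng.normal(0, np.sqrt(2.0 / fan_in),
                                            (c_out, c_in // groups, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride,
                         self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self._buffers = {"running_mean": np.zeros(c), "running_var": np.ones(c)}

    def forward(self, x):
        return ad.batchnorm2d(x, self.weight, self.bias,
                              self._buffers["running_mean"],
                              self._buffers["running_var"],
                              self.training, self.eps, self.momentum)


class SiLU(Module):
    def forward(self, x):
        return ad.silu(x)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class ConvBnAct(Module):
    """The standard Conv -> BatchNorm -> activation block (SiLU default)."""

    def __init__(self, c_in, c_out, k=3, stride=1, padding=None, groups=1, act="silu"):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.act = {"silu": ad.silu, "relu": ad.relu, "none": lambda t: t}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Upsample2x(Module):
    def forward(self, x):
        _, _, h, w = x.shape
        return ad.resize_nearest(x, (2 * h, 2 * w))


class Adam:
    """Adam with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(path, model: Module, config: dict) -> None:
    """Checkpoint layout: npz of arrays plus a JSON config entry."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path):
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    return state, cfg
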