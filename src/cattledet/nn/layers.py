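"""Neural-network modules (convolutions, normalization, containers).

Conventions follow the YOLO ecosystem: ``ConvBNAct`` is a bias-free
convolution + BatchNorm + activation; group-normalized convolutions
(``ConvGNAct``) are used in the detection head where batch-size
independence matters.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter registration via attribute assignment."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for name, m in self._modules.items():
            yield from m.named_modules(prefix=f"{prefix}{name}.")

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                out[f"{name}.running_mean"] = m.running_mean.copy()
                out[f"{name}.running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(sd[name], dtype=p.data.dtype).reshape(p.shape)
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(sd[f"{name}.running_mean"]).copy()
                m.running_var = np.asarray(sd[f"{name}.running_var"]).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Module):
    """Plain 2-D convolution; He-normal weight init, zero bias."""

    def __init__(self, c_in, c_out, k=1, s=1, p=None, d=1, groups=1, bias=True, rng=None):
        super().__init__()
        kh, kw = _pair(k)
        if p is None:
            dh, dw = _pair(d)
            p = ((dh * (kh - 1)) // 2, (dw * (kw - 1)) // 2)  # 'same' for stride 1
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s, self.p, self.d, self.groups = _pair(k), _pair(s), _pair(p), _pair(d), groups
        fan_in = (c_in // groups) * kh * kw
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in // groups, kh, kw))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.s, self.p, self.d, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03, zero_init=False):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        g0 = 0.0 if zero_init else 1.0
        self.gamma = Tensor(np.full(c, g0, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if ag._TRACE is not None:
            ag._TRACE.append(("batchnorm", 0, 0))
            return x
        g = self.gamma.reshape(1, self.c, 1, 1)
        b = self.beta.reshape(1, self.c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, self.c, 1, 1)
            sd = 1.0 / np.sqrt(self.running_var.reshape(1, self.c, 1, 1) + self.eps)
            xn = (x - mu) * sd
        return xn * g + b


class GroupNorm(Module):
    def __init__(self, groups, c, eps=1e-5):
        super().__init__()
        if c % groups:
            raise ValueError(f"channels {c} not divisible by {groups} groups")
        self.groups, self.c, self.eps = groups, c, eps
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if ag._TRACE is not None:
            ag._TRACE.append(("groupnorm", 0, 0))
            return x
        N, C, H, W = x.shape
        xg = x.reshape(N, self.groups, (C // self.groups) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = ((xg - mu) * (var + self.eps) ** -0.5).reshape(N, C, H, W)
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class ConvBNAct(Module):
    """conv (no bias) + BatchNorm + activation — the YOLO 'Conv' block."""

    def __init__(self, c_in, c_out, k=1, s=1, p=None, d=1, groups=1, act="silu", zero_init_bn=False, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, s, p, d, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out, zero_init=zero_init_bn)
        self.act = {"silu": SiLU, "relu6": ReLU6, "none": Identity}[act]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class ConvGNAct(Module):
    """conv (no bias) + GroupNorm + SiLU — head building block."""

    def __init__(self, c_in, c_out, k=1, gn_groups=16, act="silu", rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, 1, None, 1, 1, bias=False, rng=rng)
        self.gn = GroupNorm(gn_groups, c_out)
        self.act = {"silu": SiLU, "none": Identity}[act]()

    def forward(self, x):
        return self.act(self.gn(self.conv(x)))


class MaxPool2d(Module):
    def __init__(self, k, s=1, p=None):
        super().__init__()
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p

    def forward(self, x):
        return ag.max_pool2d(x, self.k, self.s, self.p)


class Upsample2(Module):
    def forward(self, x):
        return ag.upsample_nearest2(x)


class Scale(Module):
    """Per-level learnable scalar multiplier (FCOS-style), init 1."""

    def __init__(self, init=1.0):
        super().__init__()
        self.s = Tensor(np.array([init], dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return x * self.s.reshape(1, 1, 1, 1)
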