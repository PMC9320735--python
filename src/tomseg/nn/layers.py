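"""Layer modules over the autodiff core: parameter registration, train/eval
mode, weight initialization and (de)serialization to flat name->array dicts."""
from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU", "ReLU6",
    "UpsampleBilinear", "ConvTranspose2d", "Dropout", "Add",
]


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    # -- mode / grad -------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- state dict --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                own[name].data = np.asarray(arr, dtype=np.float32).reshape(own[name].data.shape)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing entries in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, *, stride: int = 1,
                 dilation: int = 1, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError(
                f"groups={groups} must divide c_in={c_in} and c_out={c_out}")
        rng = rng or np.random.default_rng()
        fan_in = (c_in // groups) * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(c_out, c_in // groups, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.dilation, self.groups = stride, dilation, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        dilation=self.dilation, groups=self.groups)


class ConvTranspose2d(Module):
    """Learned upsampling, kernel == stride == factor."""

    def __init__(self, c_in: int, c_out: int, factor: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, factor, factor))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.factor = factor

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, factor=self.factor)


class BatchNorm2d(Module):
    def __init__(self, c: int, *, affine: bool = True, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        if affine:
            self.weight = Tensor(np.ones(c), requires_grad=True)
            self.bias = Tensor(np.zeros(c), requires_grad=True)
        else:
            self.weight = self.bias = None
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)


class UpsampleBilinear(Module):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        H, W = x.data.shape[2:]
        return F.resize_bilinear(x, (H * self.factor, W * self.factor))


class Dropout(Module):
    """Active only in training mode; draws from a reseedable generator."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self.reseed(seed)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        return F.dropout(x, self.p, self.rng, self.training)


class Add(Module):
    def forward(self, a, b):
        return F.add(a, b)
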