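"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm_2d, conv2d

__all__ = ["Module", "ModuleList", "Sequential", "Conv2d", "BatchNorm2d", "Linear"]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item
            elif isinstance(value, dict):
                for k, item in value.items():
                    key = "_".join(map(str, k)) if isinstance(k, tuple) else str(k)
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{key}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{key}", item
                    elif isinstance(item, (list, tuple)):
                        for i, sub in enumerate(item):
                            if isinstance(sub, Tensor) and sub.requires_grad:
                                yield f"{full}.{key}.{i}", sub

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ----------------------------------------------------------------- state
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value._named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}.")

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:") :]
                if name not in buffers:
                    raise KeyError(f"unknown buffer {name!r} in state dict")
                buffers[name][...] = value
            else:
                if key not in params:
                    raise KeyError(f"unknown parameter {key!r} in state dict")
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: "
                        f"model {params[key].data.shape}, state {value.shape}"
                    )
                params[key].data = value.astype(params[key].data.dtype, copy=True)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, module):
        self.items.append(module)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)


class Conv2d(Module):
    """3x3 / 1x1 convolution with He-normal initialization."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W); running statistics used in eval mode."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x):
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return batch_norm_2d(x, self.gamma, self.beta, mu, var, self.eps, batch_stats=True)
        return batch_norm_2d(x, self.gamma, self.beta,
                             self.running_mean.astype(x.dtype),
                             self.running_var.astype(x.dtype), self.eps, batch_stats=False)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None, std=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        if std is None:
            std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_features, out_features)).astype(dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias
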