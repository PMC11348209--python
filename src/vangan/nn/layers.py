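"""Neural network building blocks (modules, convolutions, normalisation)."""
from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Conv3d", "InstanceNorm3d",
           "SpatialDropout3d", "Sequential"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: tracks parameters and sub-modules by name."""

    def __init__(self):
        self._params: Dict[str, Parameter] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def checksum(self) -> float:
        """Deterministic scalar summary of all parameters (for tests)."""
        return float(sum(np.float64(p.data).sum() for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Module):
    """3-D convolution with He-normal init and optional same-size padding.

    ``padding='same'`` reflect-pads so the output spatial extent equals
    ``ceil(extent / stride)`` (for stride 1, identical extent); kernels with
    even size pad one voxel more on the trailing side.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: str = "same",
                 pad_mode: str = "reflect", bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = int(kernel_size)
        fan_in = in_channels * k ** 3
        std = np.sqrt(2.0 / fan_in)  # He-normal
        self.weight = Parameter(rng.normal(
            0.0, std, size=(k, k, k, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = int(stride)
        self.kernel_size = k
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x: Tensor) -> Tensor:
        if self.padding == "same":
            k, s = self.kernel_size, self.stride
            pads = []
            for extent in x.shape[1:4]:
                out_extent = -(-extent // s)  # ceil
                total = max((out_extent - 1) * s + k - extent, 0)
                pads.append((total // 2, total - total // 2))
            x = F.pad3d(x, pads, mode=self.pad_mode)
        elif self.padding != "valid":
            raise ValueError("padding must be 'same' or 'valid'")
        return F.conv3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes (channels last)."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.channels = channels
        if affine:
            self.gamma = Parameter(np.ones(channels))
            self.beta = Parameter(np.zeros(channels))
        else:
            self.gamma = None
            self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class SpatialDropout3d(Module):
    """Channel-wise dropout; inactive in eval mode. Needs an explicit rng."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.rate == 0.0 or rng is None:
            return x
        n, c = x.shape[0], x.shape[-1]
        keep = (rng.random((n, 1, 1, 1, c)) >= self.rate)
        scale = keep.astype(x.data.dtype) / (1.0 - self.rate)
        return x * Tensor(scale)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._order: List[str] = []
        for i, m in enumerate(modules):
            name = f"m{i}"
            setattr(self, name, m)
            self._order.append(name)

    def forward(self, x: Tensor) -> Tensor:
        for name in self._order:
            x = getattr(self, name)(x)
        return x
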