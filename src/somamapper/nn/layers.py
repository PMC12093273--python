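"""Neural-network modules built on the autograd engine.

Convolutions support 2D and 3D inputs through a shared N-dimensional
implementation; batch normalization keeps running statistics so inference
is deterministic regardless of batch composition.
"""

from __future__ import annotations

import json

import numpy as np

from .autograd import Tensor, conv_nd, conv_transpose2x_3d


class Module:
    """Base class: parameter discovery, train/eval mode, (de)serialization."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _modules(self) -> list["Module"]:
        mods = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.append(v)
            elif isinstance(v, (list, tuple)):
                mods.extend(m for m in v if isinstance(m, Module))
        return mods

    def train(self):
        self.training = True
        for m in self._modules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._modules():
            m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # Flat state dict: parameter order is definition order, which is stable
    # for a fixed architecture/config.
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        arrays += [b for b in self._buffers()]
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        bufs = self._buffer_slots()
        if len(arrays) != len(params) + len(bufs):
            raise ValueError(
                f"state size mismatch: got {len(arrays)} arrays, "
                f"expected {len(params) + len(bufs)}"
            )
        for p, a in zip(params, arrays[: len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = a.astype(np.float32)
        for (mod, name), a in zip(bufs, arrays[len(params):]):
            setattr(mod, name, a.astype(np.float32))

    def _buffers(self) -> list[np.ndarray]:
        return [getattr(m, n) for m, n in self._buffer_slots()]

    def _buffer_slots(self) -> list[tuple["Module", str]]:
        slots = []
        if isinstance(self, BatchNorm):
            slots += [(self, "running_mean"), (self, "running_var")]
        for m in self._modules():
            slots.extend(m._buffer_slots())
        return slots

    def save(self, path: str, config: dict | None = None) -> None:
        """Write weights to `path` (.npz) and a JSON config sidecar."""
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, **arrays)
        if config is not None:
            sidecar = str(path)
            sidecar = sidecar[: -len(".npz")] if sidecar.endswith(".npz") else sidecar
            with open(sidecar + ".json", "w") as fh:
                json.dump(config, fh, indent=2)

    def load(self, path: str) -> None:
        with np.load(path) as npz:
            arrays = [npz[f"arr_{i}"] for i in range(len(npz.files))]
        self.load_state_arrays(arrays)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv(Module):
    """N-dimensional convolution (2D or 3D inferred from input rank)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, nd: int,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel ** nd
        self.weight = Tensor(
            _he_init(rng, (out_ch, in_ch) + (kernel,) * nd, fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2x3D(Module):
    """Stride-2 kernel-2 transposed 3D convolution: exact 2x upsampling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            _he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch * 8), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x_3d(x, self.weight, self.bias)


class BatchNorm(Module):
    """Batch normalization over batch + spatial axes of an (N, C, ...) tensor."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            ).astype(np.float32)
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mu = self.running_mean.reshape(bshape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(bshape) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class LayerNorm(Module):
    """Normalization over the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xhat = centered * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (in_f, out_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the repeating unit of both networks."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, nd: int,
                 stride: int = 1, padding: int = 0, rng=None):
        super().__init__()
        self.conv = Conv(in_ch, out_ch, kernel, nd, stride, padding, rng)
        self.bn = BatchNorm(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
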