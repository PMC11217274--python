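"""Layers, parameter containers and the Adam optimizer for the engine in
:mod:`hazecycle._autodiff`."""

from __future__ import annotations

import numpy as np

from ._autodiff import (Tensor, batch_norm_eval, batch_norm_train, conv2d,
                        dilate2d, pad2d)

__all__ = ["Parameter", "Module", "Conv2d", "ConvTranspose2d",
           "InstanceNorm2d", "BatchNorm2d", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module container: tracks parameters, buffers and submodules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._mods.items():
            yield from m.named_parameters(prefix + k + ".")

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._mods.items():
            yield from m.named_buffers(prefix + k + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        object.__setattr__(self, "training", True)
        for m in self._mods.values():
            m.train()
        return self

    def eval(self):
        object.__setattr__(self, "training", False)
        for m in self._mods.values():
            m.eval()
        return self

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for k, buf in self.named_buffers():
            for bk, bv in buf.items():
                state[f"{k}.{bk}"] = np.asarray(bv).copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k], dtype=np.float32).copy()
        for k, buf in self.named_buffers():
            for bk in buf:
                buf[bk] = np.asarray(state[f"{k}.{bk}"],
                                     dtype=np.float32).copy()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Convolution with same/valid padding; weights ~ N(0, 0.02)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "zero", bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode
        self.weight = Parameter(rng.normal(0.0, 0.02, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.pad:
            x = pad2d(x, (self.pad,) * 4, mode=self.pad_mode)
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    """Stride-2, kernel-3 transposed convolution that exactly doubles H and W.

    Realised as zero-dilation + asymmetric padding + valid correlation, so
    its backward pass falls out of the primitive ops.
    """

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, 0.02, (cout, cin, 3, 3)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        up = pad2d(dilate2d(x, 2), (1, 2, 1, 2))
        return conv2d(up, self.weight, self.bias, stride=1)


class InstanceNorm2d(Module):
    def __init__(self, c: int):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))

    def __call__(self, x: Tensor) -> Tensor:
        from ._autodiff import instance_norm
        return instance_norm(x, self.gamma, self.beta)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.momentum = momentum
        self._buffers["running"] = {"mean": np.zeros(c, np.float32),
                                    "var": np.ones(c, np.float32)}

    def __call__(self, x: Tensor) -> Tensor:
        running = self._buffers["running"]
        if self.training:
            return batch_norm_train(x, self.gamma, self.beta, running,
                                    self.momentum)
        return batch_norm_eval(x, self.gamma, self.beta, running)


class Adam:
    """Adam with externally supplied learning rate (set per step)."""

    def __init__(self, params, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        if lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a, np.float32).copy() for a in state["m"]]
        self.v = [np.asarray(a, np.float32).copy() for a in state["v"]]
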