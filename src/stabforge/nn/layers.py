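"""Layers and optimizers for the numpy autodiff core."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .tensor import Tensor, concat, conv1d_valid


class Module:
    """Base class: tracks parameters as named tensors for optimizers and
    checkpointing."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
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

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                state[name] = v.data.copy()
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    state[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            state[f"{name}.{i}.{k}"] = arr
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = state[name].copy()
            elif isinstance(v, Module):
                sub = {k[len(name) + 1 :]: a for k, a in state.items()
                       if k.startswith(name + ".")}
                v.load_state_dict(sub)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        prefix = f"{name}.{i}."
                        sub = {k[len(prefix):]: a for k, a in state.items()
                               if k.startswith(prefix)}
                        item.load_state_dict(sub)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    fan_in = int(np.prod(shape[:-1])) or 1
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Valid 1-D convolution, channels-last: (B, L, C_in) -> (B, L-w+1, C_out)."""

    def __init__(self, width: int, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = glorot(rng, width, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_valid(x, self.w, self.b)


class LSTMCell(Module):
    """Standard LSTM cell; gates packed as [i, f, g, o]."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.wx = glorot(rng, n_in, 4 * n_hidden)
        self.wh = glorot(rng, n_hidden, 4 * n_hidden)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias starts open
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        n = self.n_hidden
        z = x @ self.wx + h @ self.wh + self.b
        i = z[:, 0 * n : 1 * n].sigmoid()
        f = z[:, 1 * n : 2 * n].sigmoid()
        g = z[:, 2 * n : 3 * n].tanh()
        o = z[:, 3 * n : 4 * n].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class SGD:
    def __init__(self, params: List[Tensor], lr: float = 0.1):
        self.params, self.lr = params, lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam(SGD):
    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adadelta(SGD):
    """Adadelta with accumulated squared gradients and updates."""

    def __init__(self, params: List[Tensor], lr: float = 1.0,
                 rho: float = 0.95, eps: float = 1e-6):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.eg = [np.zeros_like(p.data) for p in params]
        self.ed = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self.eg, self.ed):
            if p.grad is None:
                continue
            eg *= self.rho
            eg += (1 - self.rho) * p.grad**2
            delta = np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * p.grad
            ed *= self.rho
            ed += (1 - self.rho) * delta**2
            p.data -= self.lr * delta
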