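"""Neural layers built on the autodiff core.

Layers hold parameters as :class:`~chronomt.nn.autodiff.Tensor` objects and
expose ``parameters()`` for the optimizer.  Initialization follows the usual
fan-in–scaled uniform scheme (what deep-learning frameworks use for linear
and recurrent layers by default), drawn from an explicit ``numpy`` generator
so every model is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, relu, sigmoid, stack, tanh

__all__ = [
    "Module",
    "Dense",
    "Dropout",
    "RNNCell",
    "GRUCell",
    "LSTMCell",
    "Recurrent",
    "make_cell",
]


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
            elif isinstance(value, dict):
                for item in value.values():
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
            elif isinstance(value, dict):
                for item in value.values():
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("state array count does not match parameter count")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.copy()


class Dense(Module):
    """Affine map on the last axis.

    Applied to a ``[N, T, F]`` input this is exactly a 1x1 convolution along
    the wave axis: one kernel touches one time step.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.n_in, self.n_out = n_in, n_out
        self.weight = _uniform(rng, n_in, (n_in, n_out))
        self.bias = _uniform(rng, n_in, (n_out,))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self._rng.random(x.shape) < keep
        return x * (mask / keep)


class RNNCell(Module):
    """Elman recurrence: h_t = tanh(x_t W_x + h_{t-1} W_h + b)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.w_x = _uniform(rng, n_in, (n_in, n_hidden))
        self.w_h = _uniform(rng, n_hidden, (n_hidden, n_hidden))
        self.bias = _uniform(rng, n_hidden, (n_hidden,))

    def init_state(self, n: int):
        return (Tensor(np.zeros((n, self.n_hidden))),)

    def step(self, x_t: Tensor, state):
        (h,) = state
        h_new = tanh(x_t @ self.w_x + h @ self.w_h + self.bias)
        return h_new, (h_new,)


class GRUCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.w_x = _uniform(rng, n_in, (n_in, 3 * n_hidden))
        self.w_h = _uniform(rng, n_hidden, (n_hidden, 3 * n_hidden))
        self.bias = _uniform(rng, n_hidden, (3 * n_hidden,))

    def init_state(self, n: int):
        return (Tensor(np.zeros((n, self.n_hidden))),)

    def step(self, x_t: Tensor, state):
        (h,) = state
        H = self.n_hidden
        gx = x_t @ self.w_x + self.bias
        gh = h @ self.w_h
        r = sigmoid(gx[:, :H] + gh[:, :H])
        z = sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
        n_ = tanh(gx[:, 2 * H :] + r * gh[:, 2 * H :])
        h_new = (1.0 - z) * n_ + z * h
        return h_new, (h_new,)


class LSTMCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.w_x = _uniform(rng, n_in, (n_in, 4 * n_hidden))
        self.w_h = _uniform(rng, n_hidden, (n_hidden, 4 * n_hidden))
        self.bias = _uniform(rng, n_hidden, (4 * n_hidden,))

    def init_state(self, n: int):
        z = np.zeros((n, self.n_hidden))
        return (Tensor(z), Tensor(z.copy()))

    def step(self, x_t: Tensor, state):
        h, c = state
        H = self.n_hidden
        g = x_t @ self.w_x + h @ self.w_h + self.bias
        i = sigmoid(g[:, :H])
        f = sigmoid(g[:, H : 2 * H])
        o = sigmoid(g[:, 2 * H : 3 * H])
        g_ = tanh(g[:, 3 * H :])
        c_new = f * c + i * g_
        h_new = o * tanh(c_new)
        return h_new, (h_new, c_new)


_CELLS = {"RNN": RNNCell, "GRU": GRUCell, "LSTM": LSTMCell}


def make_cell(kind: str, n_in: int, n_hidden: int, rng: np.random.Generator):
    try:
        cls = _CELLS[kind.upper()]
    except KeyError:
        raise ValueError(f"unknown cell type {kind!r}; expected one of {sorted(_CELLS)}")
    return cls(n_in, n_hidden, rng)


class Recurrent(Module):
    """Run a recurrent cell over the time axis of a [N, T, F] tensor."""

    def __init__(self, cell):
        self.cell = cell

    def __call__(self, x: Tensor) -> Tensor:
        n, t_steps = x.shape[0], x.shape[1]
        state = self.cell.init_state(n)
        outputs = []
        for t in range(t_steps):
            h, state = self.cell.step(x[:, t, :], state)
            outputs.append(h)
        return stack(outputs, axis=1)
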