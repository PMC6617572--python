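"""Layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad``.  Frozen parameters
still receive gradients (cheap) but optimizers skip their update, and
``Param.frozen`` is what the transfer-learning freeze masks toggle.
"""

from __future__ import annotations

import numpy as np

from .init import lecun_uniform


class Param:
    """A trainable tensor with its gradient accumulator and freeze flag."""

    __slots__ = ("name", "value", "grad", "frozen")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.frozen = False

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    name: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    @property
    def output_dim(self) -> int:
        raise NotImplementedError


class Identity(Layer):
    """Pass-through channel for precomputed feature vectors."""

    def __init__(self, dim: int, name: str = "identity"):
        self.name = name
        self._dim = dim

    def forward(self, x, train=False, rng=None):
        return x

    def backward(self, grad):
        return grad

    @property
    def output_dim(self) -> int:
        return self._dim


def _elu(z, alpha):
    return np.where(z >= 0, z, alpha * np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z, a, alpha):
    # for z<0, d/dz alpha*(e^z - 1) = alpha*e^z = a + alpha
    return np.where(z >= 0, 1.0, a + alpha)


class Dense(Layer):
    """Fully connected layer with optional ELU/ReLU activation."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str = "linear",
        elu_alpha: float = 1.0,
        rng: np.random.Generator | None = None,
        name: str = "dense",
    ):
        if n_in < 1 or n_out < 1:
            raise ValueError("dense layer dimensions must be positive")
        if activation not in ("linear", "elu", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng()
        self.name = name
        self.activation = activation
        self.elu_alpha = elu_alpha
        self.W = Param(f"{name}/W", lecun_uniform(n_in, (n_in, n_out), rng))
        self.b = Param(f"{name}/b", np.zeros(n_out))
        self._x = None
        self._z = None
        self._a = None

    def params(self):
        return [self.W, self.b]

    def reinitialize(self, rng: np.random.Generator) -> None:
        n_in = self.W.value.shape[0]
        self.W.value = lecun_uniform(n_in, self.W.value.shape, rng)
        self.b.value = np.zeros_like(self.b.value)

    def forward(self, x, train=False, rng=None):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "elu":
            a = _elu(z, self.elu_alpha)
        elif self.activation == "relu":
            a = np.maximum(z, 0.0)
        else:
            a = z
        self._z, self._a = z, a
        return a

    def backward(self, grad):
        if self.activation == "elu":
            dz = grad * _elu_grad(self._z, self._a, self.elu_alpha)
        elif self.activation == "relu":
            dz = grad * (self._z > 0)
        else:
            dz = grad
        self.W.grad += self._x.reshape(-1, self._x.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
        self.b.grad += dz.reshape(-1, dz.shape[-1]).sum(axis=0)
        return dz @ self.W.value.T

    @property
    def output_dim(self):
        return self.W.value.shape[1]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.name = name
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    @property
    def output_dim(self):
        raise AttributeError("dropout preserves its input dimension")


class OneHot(Layer):
    """Token indices (B, L) -> one-hot floats (B, L, V); pad index V -> zero row."""

    def __init__(self, vocab_size: int, name: str = "onehot"):
        self.name = name
        self.vocab_size = vocab_size
        self._eye = np.vstack([np.eye(vocab_size), np.zeros((1, vocab_size))])

    def forward(self, x, train=False, rng=None):
        return self._eye[x]

    def backward(self, grad):
        return None  # token indices are data, not differentiable

    @property
    def output_dim(self):
        return self.vocab_size


class Embedding(Layer):
    """Trainable token embedding; pad index V maps to a constant zero row.

    Equivalent to multiplying the one-hot matrix by the weight table, so a
    padding position (all-zero one-hot row) contributes a zero vector and
    no gradient.
    """

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator | None = None,
                 name: str = "embedding"):
        rng = rng or np.random.default_rng()
        self.name = name
        self.vocab_size = vocab_size
        self.dim = dim
        self.W = Param(f"{name}/W", lecun_uniform(vocab_size, (vocab_size, dim), rng))
        self._x = None

    def params(self):
        return [self.W]

    def reinitialize(self, rng: np.random.Generator) -> None:
        self.W.value = lecun_uniform(self.vocab_size, self.W.value.shape, rng)

    def forward(self, x, train=False, rng=None):
        self._x = x
        full = np.vstack([self.W.value, np.zeros((1, self.dim))])
        return full[x]

    def backward(self, grad):
        dfull = np.zeros((self.vocab_size + 1, self.dim))
        np.add.at(dfull, self._x, grad)
        self.W.grad += dfull[: self.vocab_size]
        return None

    @property
    def output_dim(self):
        return self.dim


class Conv1D(Layer):
    """Dilated 1-D convolution with valid padding.

    Input (B, L, C) -> output (B, L - (k-1)*dilation, filters).  The
    receptive-field check across a stack lives in the model builder.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel_size: int,
        dilation: int = 1,
        activation: str = "elu",
        elu_alpha: float = 1.0,
        rng: np.random.Generator | None = None,
        name: str = "conv1d",
    ):
        rng = rng or np.random.default_rng()
        self.name = name
        self.filters = filters
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.activation = activation
        self.elu_alpha = elu_alpha
        fan_in = kernel_size * in_channels
        self.W = Param(f"{name}/W", lecun_uniform(fan_in, (fan_in, filters), rng))
        self.b = Param(f"{name}/b", np.zeros(filters))
        self._xw = None
        self._z = None
        self._a = None
        self._in_shape = None

    def params(self):
        return [self.W, self.b]

    def reinitialize(self, rng: np.random.Generator) -> None:
        fan_in = self.W.value.shape[0]
        self.W.value = lecun_uniform(fan_in, self.W.value.shape, rng)
        self.b.value = np.zeros_like(self.b.value)

    def _window_index(self, L: int) -> np.ndarray:
        out_len = L - (self.kernel_size - 1) * self.dilation
        if out_len < 1:
            raise ValueError(
                f"receptive span {(self.kernel_size - 1) * self.dilation + 1} "
                f"exceeds input length {L}"
            )
        return np.arange(out_len)[:, None] + self.dilation * np.arange(self.kernel_size)[None, :]

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        idx = self._window_index(L)
        xw = x[:, idx, :].reshape(B, idx.shape[0], -1)  # (B, out, k*C)
        z = xw @ self.W.value + self.b.value
        if self.activation == "elu":
            a = _elu(z, self.elu_alpha)
        elif self.activation == "relu":
            a = np.maximum(z, 0.0)
        else:
            a = z
        self._xw, self._z, self._a, self._in_shape = xw, z, a, (B, L, C)
        return a

    def backward(self, grad):
        if self.activation == "elu":
            dz = grad * _elu_grad(self._z, self._a, self.elu_alpha)
        elif self.activation == "relu":
            dz = grad * (self._z > 0)
        else:
            dz = grad
        B, L, C = self._in_shape
        out_len = dz.shape[1]
        self.W.grad += np.einsum("bok,bof->kf", self._xw, dz)
        self.b.grad += dz.sum(axis=(0, 1))
        dxw = (dz @ self.W.value.T).reshape(B, out_len, self.kernel_size, C)
        dx = np.zeros((B, L, C))
        for j in range(self.kernel_size):
            start = j * self.dilation
            dx[:, start : start + out_len, :] += dxw[:, :, j, :]
        return dx

    @property
    def output_dim(self):
        return self.filters


class GlobalMaxPool1D(Layer):
    """(B, L, C) -> (B, C) taking the per-channel maximum over positions."""

    def __init__(self, channels: int, name: str = "gmaxpool"):
        self.name = name
        self._channels = channels
        self._argmax = None
        self._in_shape = None

    def forward(self, x, train=False, rng=None):
        self._argmax = np.argmax(x, axis=1)
        self._in_shape = x.shape
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]

    def backward(self, grad):
        dx = np.zeros(self._in_shape)
        np.put_along_axis(dx, self._argmax[:, None, :], grad[:, None, :], axis=1)
        return dx

    @property
    def output_dim(self):
        return self._channels


class LSTM(Layer):
    """Single-layer LSTM emitting the final hidden state.

    Gate order in the packed weight matrices is (input, forget, candidate,
    output); the forget-gate bias starts at ``forget_bias`` (default 1.0)
    so the cell initially remembers.
    """

    def __init__(
        self,
        input_dim: int,
        units: int,
        rng: np.random.Generator | None = None,
        reverse: bool = False,
        forget_bias: float = 1.0,
        name: str = "lstm",
    ):
        rng = rng or np.random.default_rng()
        self.name = name
        self.units = units
        self.reverse = reverse
        self.W = Param(f"{name}/W", lecun_uniform(input_dim, (input_dim, 4 * units), rng))
        self.U = Param(f"{name}/U", lecun_uniform(units, (units, 4 * units), rng))
        b = np.zeros(4 * units)
        b[units : 2 * units] = forget_bias
        self.b = Param(f"{name}/b", b)
        self._forget_bias = forget_bias
        self._cache = None

    def params(self):
        return [self.W, self.U, self.b]

    def reinitialize(self, rng: np.random.Generator) -> None:
        self.W.value = lecun_uniform(self.W.value.shape[0], self.W.value.shape, rng)
        self.U.value = lecun_uniform(self.U.value.shape[0], self.U.value.shape, rng)
        b = np.zeros_like(self.b.value)
        b[self.units : 2 * self.units] = self._forget_bias
        self.b.value = b

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))

    def forward(self, x, train=False, rng=None):
        if self.reverse:
            x = x[:, ::-1, :]
        B, L, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        steps = []
        for t in range(L):
            z = x[:, t, :] @ self.W.value + h @ self.U.value + self.b.value
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = self._sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            steps.append((x[:, t, :], h, c, i, f, g, o, tanh_c))
            h = o * tanh_c
            c = c_new
        self._cache = (steps, x.shape)
        return h

    def backward(self, grad):
        steps, (B, L, D) = self._cache
        u = self.units
        dh = grad
        dc = np.zeros((B, u))
        dx = np.zeros((B, L, D))
        for t in range(L - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = steps[t]
            do = dh * tanh_c
            dct = dc + dh * o * (1.0 - tanh_c**2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.W.grad += x_t.T @ dz
            self.U.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.value.T
            dh = dz @ self.U.value.T
            dc = dct * f
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx

    @property
    def output_dim(self):
        return self.units


class BLSTM(Layer):
    """Bidirectional LSTM: forward and backward final states concatenated."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator | None = None,
                 forget_bias: float = 1.0, name: str = "blstm"):
        rng = rng or np.random.default_rng()
        self.name = name
        self.fwd = LSTM(input_dim, units, rng, reverse=False, forget_bias=forget_bias,
                        name=f"{name}/fwd")
        self.bwd = LSTM(input_dim, units, rng, reverse=True, forget_bias=forget_bias,
                        name=f"{name}/bwd")
        self.units = units

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def reinitialize(self, rng: np.random.Generator) -> None:
        self.fwd.reinitialize(rng)
        self.bwd.reinitialize(rng)

    def forward(self, x, train=False, rng=None):
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=1)

    def backward(self, grad):
        u = self.units
        dx = self.fwd.backward(grad[:, :u])
        dx = dx + self.bwd.backward(grad[:, u:])
        return dx

    @property
    def output_dim(self):
        return 2 * self.units


class Sequential(Layer):
    """Chains layers; backward stops early on non-differentiable inputs."""

    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.name = name
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                return None
        return grad

    @property
    def output_dim(self):
        for layer in reversed(self.layers):
            try:
                return layer.output_dim
            except AttributeError:
                continue
        raise AttributeError("no layer exposes an output dimension")
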