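"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the adversarial models need: affine layers,
LeakyReLU / tanh / sigmoid activations, batch normalization, LSTM cells
(expressed per-timestep through column slicing, so every tensor stays 2-D),
elementwise arithmetic, reductions, and an Adam optimizer.

Gradients flow through a tape built implicitly by the forward pass; calling
``backward()`` on a scalar loss runs the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Dense", "BatchNorm", "LSTMLayer", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities --------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * (1.0 - y**2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y * (1.0 - y))
        return out

    def leaky_relu(self, slope: float):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def square(self):
        out = Tensor(self.data**2, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(2.0 * g * self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(0.5 * g / y)
        return out

    # -- shape ops and reductions ----------------------------------------

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], parents=(self,))
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accumulate(full)
        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- backward pass ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Dense:
    """Affine layer ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.n_in, self.n_out = n_in, n_out

    def __call__(self, x: Tensor) -> Tensor:
        assert x.shape[1] == self.n_in, f"Dense expects {self.n_in} features, got {x.shape[1]}"
        return x @ self.W + self.b

    @property
    def parameters(self):
        return [self.W, self.b]

    @property
    def n_parameters(self) -> int:
        return self.n_in * self.n_out + self.n_out


class BatchNorm:
    """Batch normalization over features, Keras running-average convention.

    ``running <- momentum * running + (1 - momentum) * batch_statistic``.
    """

    def __init__(self, n_features: int, momentum: float = 0.8, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.n_features = n_features

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = (x - mu).square().mean(axis=0, keepdims=True)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta

    @property
    def parameters(self):
        return [self.gamma, self.beta]

    @property
    def n_parameters(self) -> int:
        return 2 * self.n_features


class LSTMLayer:
    """LSTM over a (batch, T * n_in) tensor laid out as T contiguous column
    blocks of width ``n_in``; gate order i, f, g, o; forget-gate bias 1.

    ``return_sequences=True`` concatenates all hidden states into a
    (batch, T * units) tensor, mirroring a flattened Keras output.
    """

    def __init__(self, n_in: int, units: int, timesteps: int,
                 rng: np.random.Generator, return_sequences: bool):
        limit = np.sqrt(6.0 / (n_in + units))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, 4 * units)), requires_grad=True)
        lim_u = np.sqrt(6.0 / (2 * units))
        self.U = Tensor(rng.uniform(-lim_u, lim_u, size=(units, 4 * units)), requires_grad=True)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.n_in, self.units, self.timesteps = n_in, units, timesteps
        self.return_sequences = return_sequences

    def __call__(self, x: Tensor) -> Tensor:
        assert x.shape[1] == self.timesteps * self.n_in, (
            f"LSTM expects {self.timesteps}x{self.n_in} columns, got {x.shape[1]}")
        n, u = x.shape[0], self.units
        h = Tensor(np.zeros((n, u)))
        c = Tensor(np.zeros((n, u)))
        outputs = []
        for t in range(self.timesteps):
            xt = x.slice_cols(t * self.n_in, (t + 1) * self.n_in)
            z = xt @ self.W + h @ self.U + self.b
            i = z.slice_cols(0, u).sigmoid()
            f = z.slice_cols(u, 2 * u).sigmoid()
            g = z.slice_cols(2 * u, 3 * u).tanh()
            o = z.slice_cols(3 * u, 4 * u).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        return concat(outputs, axis=1) if self.return_sequences else h

    @property
    def parameters(self):
        return [self.W, self.U, self.b]

    @property
    def n_parameters(self) -> int:
        return 4 * self.units * (self.n_in + self.units + 1)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
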