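"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a purpose-built tensor engine for the completion network: it
supports exactly the operations the generator/discriminator need
(broadcast arithmetic, matmul, row gathering with scatter-add backward,
axis max/sum/mean, concat/reshape, relu/sigmoid/log/sqrt) with float32
storage and a topological-order backward pass.  ``no_grad()`` disables
graph construction for inference so large forward passes free their
intermediates immediately.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=False)
        else:
            self.grad = self.grad + grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                t._backward = None  # release closures promptly

    # -- basics -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, np.float32))

    def __add__(self, other):
        other = Tensor._wrap(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        return Tensor._result(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return Tensor._result(self.data @ other.data, (self, other), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        def backward(g):
            self._accum(g.reshape(orig))
        return Tensor._result(self.data.reshape(*shape), (self,), backward)

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """out[...] = self[idx[...], :] for a 2-D tensor; scatter-add backward."""
        idx = np.asarray(idx)
        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx.ravel(), g.reshape(-1, self.data.shape[1]))
            self._accum(acc)
        return Tensor._result(self.data[idx], (self,), backward)

    @staticmethod
    def concat(tensors: list, axis: int = -1) -> "Tensor":
        datas = [t.data for t in tensors]
        splits = np.cumsum([d.shape[axis] for d in datas])[:-1]
        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        return Tensor._result(np.concatenate(datas, axis=axis), tuple(tensors), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None):
        orig = self.data.shape
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, orig).astype(np.float32))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), orig).astype(np.float32))
        return Tensor._result(self.data.sum(axis=axis), (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def max(self, axis: int):
        """Max along one axis; gradient flows to the first argmax only."""
        arg = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(arg, axis), axis=axis)
        out = np.squeeze(out, axis=axis)
        def backward(g):
            acc = np.zeros_like(self.data)
            np.put_along_axis(acc, np.expand_dims(arg, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._accum(acc)
        return Tensor._result(out, (self,), backward)

    # -- nonlinearities -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return Tensor._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))
        return Tensor._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return Tensor._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def backward(g):
            self._accum(g * 0.5 / out_data)
        return Tensor._result(out_data, (self,), backward)


class Adam:
    """Standard Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list, lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
        self.lr = float(state["lr"])
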