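"""Neural layers built on the autodiff engine: Linear, BatchNorm, fused
graph-convolution helpers, and a tiny Module container with named
parameters for checkpointing."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

try:  # compiled fused kernels; numpy fallbacks below
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

if _numba is not None:

    @_numba.njit(cache=False)
    def _edge_fwd(data, nbr, k, out):  # pragma: no cover
        n, c = data.shape
        for e in range(n * k):
            i = e // k
            j = nbr[e]
            for ch in range(c):
                ctr = data[i, ch]
                out[e, ch] = ctr
                out[e, c + ch] = data[j, ch] - ctr

    @_numba.njit(cache=False)
    def _edge_bwd(g, nbr, k, c, acc):  # pragma: no cover
        nk = g.shape[0]
        for e in range(nk):
            i = e // k
            j = nbr[e]
            for ch in range(c):
                acc[i, ch] += g[e, ch] - g[e, c + ch]
                acc[j, ch] += g[e, c + ch]

    @_numba.njit(cache=False)
    def _kmax_fwd(data, k, out, arg):  # pragma: no cover
        n, c = out.shape
        for i in range(n):
            base = i * k
            for ch in range(c):
                out[i, ch] = data[base, ch]
                arg[i, ch] = 0
            for j in range(1, k):
                row = base + j
                for ch in range(c):
                    if data[row, ch] > out[i, ch]:
                        out[i, ch] = data[row, ch]
                        arg[i, ch] = j


class Module:
    """Parameter container; children are discovered from attributes."""

    @staticmethod
    def _flatten(name: str, value):
        """Yield (key, item) pairs, descending into nested lists/tuples."""
        if isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._flatten(f"{name}.{i}", item)
        else:
            yield name, value

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            for key, item in self._flatten(f"{prefix}{name}", value):
                if isinstance(item, Tensor) and item.requires_grad:
                    out.append((key, item))
                elif isinstance(item, Module):
                    out.extend(item.named_parameters(prefix=key + "."))
        return out

    def named_buffers(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            for key, item in self._flatten(f"{prefix}{name}", value):
                if isinstance(item, Module):
                    out.extend(item.named_buffers(prefix=key + "."))
                elif (key.rsplit(".", 1)[-1].startswith("running_")
                      and isinstance(item, np.ndarray)):
                    out.append((key, item))
        return out

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        for k, v in self.named_parameters():
            v.data = np.asarray(state[k], dtype=np.float32)
        for k, _ in self.named_buffers():
            self._set_buffer(k, np.asarray(state[f"buffer:{k}"]))

    def _set_buffer(self, dotted: str, value: np.ndarray):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value)

    def train_mode(self, flag: bool = True):
        self._apply_mode(flag)

    def _apply_mode(self, flag: bool):
        for name, value in vars(self).items():
            for _, item in self._flatten(name, value):
                if isinstance(item, Module):
                    item._apply_mode(flag)
        if hasattr(self, "training"):
            self.training = flag


def batchnorm_op(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused batch normalization over axis 0 with analytic backward.

    Returns (out, mu, var); mu/var are plain arrays for running-stat
    bookkeeping.
    """
    data = x.data
    mu = data.mean(axis=0, dtype=np.float32)
    xc = data - mu
    var = np.mean(xc * xc, axis=0, dtype=np.float32)
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = xc * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.sum(axis=0))
        if x.requires_grad:
            dxhat = g * gamma.data
            x._accum(inv_std * (dxhat - dxhat.mean(axis=0)
                                - xhat * (dxhat * xhat).mean(axis=0)))

    return Tensor._result(out_data, (x, gamma, beta), backward), mu, var


def edge_features_op(x: Tensor, nbr_idx: np.ndarray, k: int) -> Tensor:
    """Fused dynamic-graph edge features concat(center, neighbor - center).

    ``x`` is (n, c); ``nbr_idx`` is flat (n*k,) and edge e = (i, nbr_idx[e])
    with i = e // k.  Output is (n*k, 2c).
    """
    data = x.data
    n, c = data.shape
    out_data = np.empty((n * k, 2 * c), dtype=np.float32)
    if _numba is not None:
        _edge_fwd(data, nbr_idx, k, out_data)
    else:
        out_data[:, :c] = np.repeat(data, k, axis=0)
        out_data[:, c:] = data[nbr_idx]
        out_data[:, c:] -= out_data[:, :c]

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        acc = np.zeros_like(data)
        if _numba is not None:
            _edge_bwd(g, nbr_idx, k, c, acc)
        else:
            acc += (g[:, :c] - g[:, c:]).reshape(n, k, c).sum(axis=1)
            np.add.at(acc, nbr_idx, g[:, c:])
        x._accum(acc)

    return Tensor._result(out_data, (x,), backward)


def kmax_aggregate_op(x: Tensor, n_groups: int, k: int) -> Tensor:
    """Channel-wise max over each group of ``k`` consecutive rows.

    ``x`` is (n_groups*k, c); output (n_groups, c).  Gradient flows to the
    first maximizing row of each group (ties broken by lowest row).
    """
    data = x.data
    c = data.shape[1]
    if _numba is not None:
        out_data = np.empty((n_groups, c), dtype=np.float32)
        arg = np.empty((n_groups, c), dtype=np.int32)
        _kmax_fwd(data, k, out_data, arg)
    else:
        grouped = data.reshape(n_groups, k, c)
        arg = np.argmax(grouped, axis=1).astype(np.int32)
        out_data = np.take_along_axis(grouped, arg[:, None, :], axis=1)[:, 0, :]

    def backward(g):
        acc = np.zeros_like(data).reshape(n_groups, k, c)
        np.put_along_axis(acc, arg[:, None, :].astype(np.int64), g[:, None, :], axis=1)
        x._accum(acc.reshape(n_groups * k, c))

    return Tensor._result(out_data, (x,), backward)


class Linear(Module):
    """Affine map with Kaiming-uniform weight initialization.

    ``bias=False`` drops the bias term (used where a following batchnorm
    would absorb it anyway).
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = np.sqrt(6.0 / n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def zero_(self):
        self.weight.data[:] = 0.0
        if self.bias is not None:
            self.bias.data[:] = 0.0


class BatchNorm(Module):
    """Batch normalization over axis 0 of an (N, C) input."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm_op(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta
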