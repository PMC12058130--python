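"""Neural-network building blocks on top of the autodiff engine.

Layers follow torch-like conventions: a :class:`Module` owns
:class:`~kanbind.nn.tensor.Parameter` leaves, ``__call__`` runs the forward
pass, ``train()``/``eval()`` toggle dropout.  Convolution, pooling and the
LSTM are fused primitives with analytic adjoints; everything else composes
the elementary ops in :mod:`kanbind.nn.tensor`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._lstm_kernels import lstm_backward_loop
from .tensor import Parameter, Tensor, _make, _sigmoid, _unbroadcast, concat

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "MaxPool1d",
    "BiLSTM",
    "LayerNorm",
    "Dropout",
    "Embedding",
    "conv1d",
    "maxpool1d",
    "lstm",
    "layer_norm",
    "bce_with_logits",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


# -- dense --------------------------------------------------------------------

class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init; layers are ReLU-adjacent
        self.weight = Parameter(rng.normal(0.0, scale, (n_in, n_out)).astype(dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# -- convolution --------------------------------------------------------------

def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid (no padding) 1-D convolution with stride 1, channels last.

    x: (N, L, C_in); weight: (C_out, C_in, K); bias: (C_out,).
    Returns (N, L-K+1, C_out).  Implemented as im2col + one GEMM; the
    channels-last layout makes the im2col gather nearly sequential.
    """
    n, L, c_in = x.data.shape
    c_out, c_in_w, k = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input {c_in}, weight {c_in_w}")
    l_out = L - k + 1
    if l_out < 1:
        raise ValueError(f"input length {L} shorter than kernel {k}")
    # windows over L: (N, L_out, C, K) -> (N, L_out, K, C) is cache-friendly
    cols = sliding_window_view(x.data, k, axis=1)
    cols2 = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(
        n * l_out, k * c_in)
    w2 = np.ascontiguousarray(weight.data.transpose(2, 1, 0)).reshape(
        k * c_in, c_out)
    out_data = (cols2 @ w2 + bias.data).reshape(n, l_out, c_out)

    def backward(g):
        g2 = g.reshape(n * l_out, c_out)
        if weight.requires_grad:
            dw = (cols2.T @ g2).reshape(k, c_in, c_out).transpose(2, 1, 0)
            weight._accumulate(dw)
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w2.T).reshape(n, l_out, k, c_in)
            dx = np.zeros_like(x.data)
            for j in range(k):  # col2im scatter-add over contiguous slabs
                dx[:, j:j + l_out, :] += dcols[:, :, j, :]
            x._accumulate(dx)

    return _make(out_data, (x, weight, bias), backward)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, (c_out, c_in, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


def maxpool1d(x: Tensor, width: int) -> Tensor:
    """Non-overlapping max pooling along the length axis (channels last).

    x: (N, L, C) -> (N, L // width, C); any remainder is dropped.  Ties
    break toward the earlier position.
    """
    n, L, c = x.data.shape
    l_out = L // width
    if l_out < 1:
        raise ValueError(f"input length {L} shorter than pool width {width}")
    trimmed = x.data[:, : l_out * width, :].reshape(n, l_out, width, c)
    if width == 2:  # the common case; avoids a slow strided argmax
        a, b = trimmed[:, :, 0, :], trimmed[:, :, 1, :]
        later = b > a
        out_data = np.where(later, b, a)
        arg = later.astype(np.int64)
    else:
        arg = trimmed.argmax(axis=2)
        out_data = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        dtrim = np.zeros((n, l_out, width, c), dtype=x.data.dtype)
        np.put_along_axis(dtrim, arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, : l_out * width, :] = dtrim.reshape(n, l_out * width, c)
        x._accumulate(dx)

    return _make(out_data, (x,), backward)


class MaxPool1d(Module):
    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.width)


# -- recurrence ---------------------------------------------------------------

def lstm(x: Tensor, w_x: Tensor, w_h: Tensor, bias: Tensor,
         peephole: Tensor | None = None) -> Tensor:
    """Unidirectional LSTM over a full sequence, returning all hidden states.

    Gate equations (i, f, o carry diagonal peephole terms on the cell state
    when ``peephole`` is given):

        i_t = sigmoid(x_t Wxi + h_{t-1} Whi + p_i * c_{t-1} + b_i)
        f_t = sigmoid(x_t Wxf + h_{t-1} Whf + p_f * c_{t-1} + b_f)
        c_t = f_t * c_{t-1} + i_t * tanh(x_t Wxc + h_{t-1} Whc + b_c)
        o_t = sigmoid(x_t Wxo + h_{t-1} Who + p_o * c_t + b_o)
        h_t = o_t * tanh(c_t)

    x: (N, T, D); w_x: (D, 4H); w_h: (H, 4H); bias: (4H,);
    peephole: (3, H) rows (p_i, p_f, p_o) or None.  Gate packing order is
    [i, f, g, o].  Returns h of shape (N, T, H).
    """
    n, T, d = x.data.shape
    h_dim = w_h.data.shape[0]
    dt = x.data.dtype
    use_peep = peephole is not None
    # input projections for every step in one GEMM; the step recursion
    # itself runs in a JIT-compiled kernel
    xp = x.data.reshape(n * T, d) @ w_x.data + bias.data
    xp = xp.reshape(n, T, 4 * h_dim)
    peep_arr = (np.ascontiguousarray(peephole.data) if use_peep
                else np.zeros((3, h_dim), dtype=dt))
    p_i, p_f, p_o = peep_arr

    H = h_dim
    i_s = np.empty((T, n, H), dtype=dt)
    f_s = np.empty_like(i_s)
    g_s = np.empty_like(i_s)
    o_s = np.empty_like(i_s)
    c_s = np.empty_like(i_s)
    tc_s = np.empty_like(i_s)
    h_all = np.empty_like(i_s)
    h = np.zeros((n, H), dtype=dt)
    c = np.zeros((n, H), dtype=dt)
    for t in range(T):
        a = xp[:, t, :] + h @ w_h.data
        a_if = a[:, : 2 * H]
        if use_peep:
            a_if = a_if + np.concatenate([c * p_i, c * p_f], axis=1)
        sig_if = _sigmoid(a_if)
        i_t = sig_if[:, :H]
        f_t = sig_if[:, H:]
        g_t = np.tanh(a[:, 2 * H: 3 * H])
        c = f_t * c + i_t * g_t
        a_o = a[:, 3 * H:]
        if use_peep:
            a_o = a_o + c * p_o
        o_t = _sigmoid(a_o)
        tc = np.tanh(c)
        h = o_t * tc
        i_s[t], f_s[t], g_s[t], o_s[t] = i_t, f_t, g_t, o_t
        c_s[t], tc_s[t], h_all[t] = c, tc, h
    out_data = np.ascontiguousarray(h_all.transpose(1, 0, 2))  # (N, T, H)

    def backward(g_out):
        g_seq = np.ascontiguousarray(g_out.transpose(1, 0, 2))
        w_h_t = np.ascontiguousarray(w_h.data.T)
        da_all, dp = lstm_backward_loop(g_seq, w_h_t, peep_arr, use_peep,
                                        i_s, f_s, g_s, o_s, c_s, tc_s)
        da_flat = da_all.reshape(T * n, 4 * h_dim)  # (T,N,·) order
        if w_x.requires_grad or x.requires_grad or bias.requires_grad:
            da2 = np.ascontiguousarray(
                da_all.transpose(1, 0, 2)).reshape(n * T, 4 * h_dim)
        if w_x.requires_grad:
            w_x._accumulate(x.data.reshape(n * T, d).T @ da2)
        if w_h.requires_grad:
            h_prev = np.concatenate(
                [np.zeros((1, n, h_dim), dtype=dt), h_all[:-1]],
                axis=0).reshape(T * n, h_dim)
            w_h._accumulate(h_prev.T @ da_flat)
        if bias.requires_grad:
            bias._accumulate(da2.sum(axis=0))
        if use_peep and peephole.requires_grad:
            peephole._accumulate(dp)
        if x.requires_grad:
            x._accumulate((da2 @ w_x.data.T).reshape(n, T, d))

    parents = (x, w_x, w_h, bias) + ((peephole,) if use_peep else ())
    return _make(out_data, parents, backward)


class BiLSTM(Module):
    """Bidirectional LSTM returning the final combined state of each pass.

    ``combine='concat'`` concatenates the two final states (dimension 2H);
    ``'sum'`` adds them (dimension H).  Peephole connections on by default,
    matching the Graves gate formulation.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 combine: str = "concat", peephole: bool = True,
                 dtype=np.float32):
        super().__init__()
        if combine not in ("concat", "sum"):
            raise ValueError(f"combine must be 'concat' or 'sum', got {combine!r}")
        self.hidden = hidden
        self.combine = combine
        self.use_peephole = peephole

        def init_dir():
            sx = np.sqrt(1.0 / d_in)
            sh = np.sqrt(1.0 / hidden)
            return (Parameter(rng.normal(0, sx, (d_in, 4 * hidden)).astype(dtype)),
                    Parameter(rng.normal(0, sh, (hidden, 4 * hidden)).astype(dtype)),
                    Parameter(np.zeros(4 * hidden, dtype=dtype)),
                    Parameter(np.zeros((3, hidden), dtype=dtype)) if peephole else None)

        self.w_x_f, self.w_h_f, self.b_f, peep_f = init_dir()
        self.w_x_b, self.w_h_b, self.b_b, peep_b = init_dir()
        if peephole:
            self.peep_f, self.peep_b = peep_f, peep_b
        else:
            self.peep_f = self.peep_b = None

    def forward(self, x: Tensor) -> Tensor:
        h_fwd = lstm(x, self.w_x_f, self.w_h_f, self.b_f, self.peep_f)
        x_rev = _reverse_time(x)
        h_bwd = lstm(x_rev, self.w_x_b, self.w_h_b, self.b_b, self.peep_b)
        last_f = _select_last(h_fwd)
        last_b = _select_last(h_bwd)
        if self.combine == "concat":
            return concat([last_f, last_b], axis=1)
        return last_f + last_b


def _reverse_time(x: Tensor) -> Tensor:
    out_data = x.data[:, ::-1, :].copy()

    def backward(g):
        x._accumulate(g[:, ::-1, :])

    return _make(out_data, (x,), backward)


def _select_last(x: Tensor) -> Tensor:
    out_data = x.data[:, -1, :].copy()

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[:, -1, :] = g
        x._accumulate(dx)

    return _make(out_data, (x,), backward)


# -- normalization / regularization -------------------------------------------

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            d = x.data.shape[-1]
            dx = inv / d * (d * gx - gx.sum(axis=-1, keepdims=True)
                            - xhat * (gx * xhat).sum(axis=-1, keepdims=True))
            x._accumulate(dx.astype(x.data.dtype))

    return _make(out_data, (x, gamma, beta), backward)


class LayerNorm(Module):
    """Layer norm with a configurable initial gain (output std at init)."""

    def __init__(self, dim: int, dtype=np.float32, gain: float = 1.0):
        super().__init__()
        self.gamma = Parameter(np.full(dim, gain, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Dropout(Module):
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Embedding(Module):
    """Token-index lookup table; optionally frozen (non-trainable)."""

    def __init__(self, table: np.ndarray, trainable: bool):
        super().__init__()
        arr = np.asarray(table)
        if trainable:
            self.weight = Parameter(arr.copy())
        else:
            self.weight = Tensor(arr.copy(), requires_grad=False)
        self.trainable = trainable

    def forward(self, idx: np.ndarray) -> Tensor:
        w = self.weight
        out_data = w.data[idx]

        def backward(g):
            dw = np.zeros_like(w.data)
            np.add.at(dw, idx, g)
            w._accumulate(dw)

        if not w.requires_grad:
            return Tensor(out_data)
        return _make(out_data, (w,), backward)


# -- losses -------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    if z.shape != y.shape:
        raise ValueError(f"logits shape {z.shape} != targets shape {y.shape}")
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray(loss.mean(), dtype=z.dtype)
    n = z.size

    def backward(g):
        logits._accumulate((g * (_sigmoid(z) - y) / n).astype(z.dtype))

    return _make(out_data, (logits,), backward)
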