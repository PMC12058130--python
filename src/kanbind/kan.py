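"""Kolmogorov-Arnold layers with per-edge B-spline activation functions.

Each edge (input i -> output j) of a layer carries its own learnable
univariate function f_{j,i}(x) = sum_k c[j,i,k] * B_k(x), expanded in a
B-spline basis on a fixed open-uniform knot grid, optionally plus a
w_b[j,i] * silu(x) base term; the layer output is the sum over inputs.  A
network is the composition of such layers.  Inputs outside the grid are
clamped to its bounds (spline term only; the silu base is global).

Pure-numpy forward functions (:func:`bspline_basis`,
:func:`kan_layer_forward`, :func:`kan_forward`) define the semantics;
:class:`KANLayer` / :class:`KAN` wrap the same arithmetic as trainable
autodiff modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.tensor import Parameter, Tensor, _make, _sigmoid

__all__ = [
    "SplineGrid",
    "KanLayerParams",
    "KanNetworkParams",
    "bspline_basis",
    "bspline_basis_and_deriv",
    "kan_layer_forward",
    "kan_forward",
    "KANLayer",
    "KAN",
]


@dataclass(frozen=True)
class SplineGrid:
    """Open-uniform cubic-by-default B-spline grid on [lower, upper].

    ``intervals`` (G) interior intervals and degree p give K = G + p basis
    functions; the knot vector repeats each boundary p+1 times so the basis
    sums to one across the whole domain.
    """

    lower: float = -1.0
    upper: float = 1.0
    intervals: int = 5
    degree: int = 3

    def __post_init__(self):
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.intervals < 1:
            raise ValueError("need at least one interval")
        if self.degree < 0:
            raise ValueError("degree must be non-negative")

    @property
    def n_basis(self) -> int:
        return self.intervals + self.degree

    @property
    def knots(self) -> np.ndarray:
        """Non-decreasing knot vector of length G + 2p + 1."""
        interior = np.linspace(self.lower, self.upper, self.intervals + 1)
        return np.concatenate([
            np.full(self.degree, self.lower), interior,
            np.full(self.degree, self.upper),
        ])


def _basis_recursion(x: np.ndarray, grid: SplineGrid, want_deriv: bool):
    """Vectorized Cox-de Boor recursion on clamped inputs.

    Returns (B, dB) with shapes (..., K); dB is None unless requested.
    The recursion runs over basis index (a dozen entries) and is vectorized
    over evaluation points.
    """
    t = grid.knots
    p = grid.degree
    g = grid.intervals
    shape = x.shape
    xf = np.clip(np.asarray(x, dtype=np.float64).ravel(),
                 grid.lower, grid.upper)
    m = xf.size
    n_int = len(t) - 1  # G + 2p degree-0 functions

    # degree 0: indicator of the containing interior interval (last closed)
    h = (grid.upper - grid.lower) / g
    idx = np.clip(np.floor((xf - grid.lower) / h).astype(np.int64), 0, g - 1)
    b = np.zeros((m, n_int))
    b[np.arange(m), idx + p] = 1.0

    prev = None
    for d in range(1, p + 1):
        nb = n_int - d
        new = np.zeros((m, nb))
        for j in range(nb):
            d1 = t[j + d] - t[j]
            d2 = t[j + d + 1] - t[j + 1]
            acc = 0.0
            if d1 > 0:
                acc = (xf - t[j]) / d1 * b[:, j]
            if d2 > 0:
                acc = acc + (t[j + d + 1] - xf) / d2 * b[:, j + 1]
            new[:, j] = acc
        prev = b
        b = new

    deriv = None
    if want_deriv:
        if p == 0:
            deriv = np.zeros_like(b)
        else:
            k = grid.n_basis
            deriv = np.zeros((m, k))
            for j in range(k):
                d1 = t[j + p] - t[j]
                d2 = t[j + p + 1] - t[j + 1]
                acc = 0.0
                if d1 > 0:
                    acc = p / d1 * prev[:, j]
                if d2 > 0:
                    acc = acc - p / d2 * prev[:, j + 1]
                deriv[:, j] = acc
        deriv = deriv.reshape(*shape, grid.n_basis)
    return b.reshape(*shape, grid.n_basis), deriv


def bspline_basis(x, grid: SplineGrid = SplineGrid()) -> np.ndarray:
    """B-spline basis values B_1..B_K at x (scalar or array, clamped)."""
    b, _ = _basis_recursion(np.asarray(x, dtype=np.float64), grid, False)
    return b


def bspline_basis_and_deriv(x, grid: SplineGrid = SplineGrid()):
    """Basis values and their derivatives d/dx at x."""
    return _basis_recursion(np.asarray(x, dtype=np.float64), grid, True)


@dataclass
class KanLayerParams:
    """Parameters of one layer: per-edge spline coefficients + base weights."""

    n_in: int
    n_out: int
    grid: SplineGrid = field(default_factory=SplineGrid)
    coef: np.ndarray | None = None          # (n_out, n_in, K)
    base_weight: np.ndarray | None = None   # (n_out, n_in)
    use_base: bool = True

    def __post_init__(self):
        k = self.grid.n_basis
        if self.coef is None:
            self.coef = np.zeros((self.n_out, self.n_in, k))
        if self.base_weight is None:
            self.base_weight = np.zeros((self.n_out, self.n_in))
        self.coef = np.asarray(self.coef, dtype=np.float64)
        self.base_weight = np.asarray(self.base_weight, dtype=np.float64)
        if self.coef.shape != (self.n_out, self.n_in, k):
            raise ValueError(
                f"coef shape {self.coef.shape} != {(self.n_out, self.n_in, k)}")
        if self.base_weight.shape != (self.n_out, self.n_in):
            raise ValueError("base_weight shape mismatch")
        if not (np.isfinite(self.coef).all()
                and np.isfinite(self.base_weight).all()):
            raise ValueError("non-finite layer parameters")


def _silu(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def kan_layer_forward(x: np.ndarray, params: KanLayerParams) -> np.ndarray:
    """out_j = sum_i [ sum_k c[j,i,k] B_k(x_i) + w_b[j,i] silu(x_i) ].

    ``x`` may be a single (n_in,) vector or an (N, n_in) batch.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != params.n_in:
        raise ValueError(f"input width {xb.shape[1]} != n_in {params.n_in}")
    k = params.grid.n_basis
    basis = bspline_basis(xb, params.grid)            # (N, n_in, K)
    flat = basis.reshape(xb.shape[0], params.n_in * k)
    out = flat @ params.coef.reshape(params.n_out, params.n_in * k).T
    if params.use_base:
        out = out + _silu(xb) @ params.base_weight.T
    return out[0] if single else out


@dataclass
class KanNetworkParams:
    """An ordered stack of layers with chained widths."""

    layers: list[KanLayerParams]

    def __post_init__(self):
        if not self.layers:
            raise ValueError("network needs at least one layer")
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if a.n_out != b.n_in:
                raise ValueError(
                    f"layer widths do not chain: {a.n_out} -> {b.n_in}")

    @property
    def widths(self) -> list[int]:
        return [self.layers[0].n_in] + [l.n_out for l in self.layers]


def kan_forward(x: np.ndarray, net: KanNetworkParams) -> np.ndarray:
    """Sequential composition of the layer maps."""
    out = np.asarray(x, dtype=np.float64)
    for layer in net.layers:
        out = kan_layer_forward(out, layer)
    return out


# -- trainable modules --------------------------------------------------------

class KANLayer(nn.Module):
    """Trainable edge-spline layer; same arithmetic as kan_layer_forward.

    Spline coefficients start as small noise, base weights at linear-layer
    scale, so an untrained layer behaves like a mildly noisy silu-linear map.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 grid: SplineGrid = SplineGrid(), use_base: bool = True,
                 dtype=np.float32):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.grid = grid
        self.use_base = use_base
        k = grid.n_basis
        self.coef = Parameter(
            rng.normal(0.0, 0.1 / np.sqrt(n_in), (n_out, n_in, k)).astype(dtype))
        self.base_weight = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_out, n_in)).astype(dtype))

    def forward(self, x: Tensor) -> Tensor:
        coef, base_w = self.coef, self.base_weight
        grid, use_base = self.grid, self.use_base
        n, n_in = x.data.shape
        k = grid.n_basis
        basis, dbasis = bspline_basis_and_deriv(x.data, grid)
        basis = basis.astype(x.data.dtype)
        dbasis = dbasis.astype(x.data.dtype)
        flat = basis.reshape(n, n_in * k)
        c2 = coef.data.reshape(self.n_out, n_in * k)
        out_data = flat @ c2.T
        if use_base:
            s = _sigmoid(x.data)
            sil = x.data * s
            out_data = out_data + sil @ base_w.data.T
        inside = ((x.data > grid.lower) & (x.data < grid.upper)).astype(x.data.dtype)

        def backward(g):
            if coef.requires_grad:
                coef._accumulate((g.T @ flat).reshape(coef.data.shape))
            if use_base and base_w.requires_grad:
                base_w._accumulate(g.T @ sil)
            if x.requires_grad:
                tmp = (g @ c2).reshape(n, n_in, k)
                dx = (tmp * dbasis).sum(axis=2) * inside
                if use_base:
                    dx = dx + (g @ base_w.data) * (s + x.data * s * (1.0 - s))
                x._accumulate(dx)

        parents = (x, coef, base_w) if use_base else (x, coef)
        return _make(out_data, parents, backward)

    def export_params(self) -> KanLayerParams:
        return KanLayerParams(n_in=self.n_in, n_out=self.n_out, grid=self.grid,
                              coef=self.coef.data.astype(np.float64),
                              base_weight=self.base_weight.data.astype(np.float64),
                              use_base=self.use_base)


class KAN(nn.Module):
    """A stack of KANLayers given widths, e.g. [fused_dim, 32, 1]."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 grid: SplineGrid = SplineGrid(), use_base: bool = True,
                 dtype=np.float32):
        super().__init__()
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.layers = [KANLayer(a, b, rng, grid=grid, use_base=use_base, dtype=dtype)
                       for a, b in zip(widths[:-1], widths[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def export_params(self) -> KanNetworkParams:
        return KanNetworkParams([l.export_params() for l in self.layers])
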