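import numpy as np
import pytest

from kanbind.kan import (KAN, KANLayer, KanLayerParams, KanNetworkParams,
                         SplineGrid, bspline_basis, bspline_basis_and_deriv,
                         kan_forward, kan_layer_forward)
from kanbind.nn.tensor import Tensor


# -- independent oracles ------------------------------------------------------

def naive_cox_de_boor(x: float, j: int, p: int, t: np.ndarray) -> float:
    """Textbook recursive B-spline evaluation, coded directly from the
    two-term recursion; deliberately slow and independent of the package."""
    if p == 0:
        # half-open intervals, except the domain's right end is closed
        # (the universal library convention, keeping sum-to-one at the bound)
        if t[j] <= x < t[j + 1]:
            return 1.0
        if x == t[-1] and t[j] < t[j + 1] == t[-1]:
            return 1.0
        return 0.0
    out = 0.0
    d1 = t[j + p] - t[j]
    if d1 > 0:
        out += (x - t[j]) / d1 * naive_cox_de_boor(x, j, p - 1, t)
    d2 = t[j + p + 1] - t[j + 1]
    if d2 > 0:
        out += (t[j + p + 1] - x) / d2 * naive_cox_de_boor(x, j + 1, p - 1, t)
    return out


def brute_force_layer(x: np.ndarray, params: KanLayerParams) -> np.ndarray:
    """Double loop over edges, naive basis per edge: the spline-sum map
    written as literally as possible."""
    t = params.grid.knots
    p = params.grid.degree
    out = np.zeros(params.n_out)
    for j in range(params.n_out):
        for i in range(params.n_in):
            xi = float(np.clip(x[i], params.grid.lower, params.grid.upper))
            for k in range(params.grid.n_basis):
                out[j] += params.coef[j, i, k] * naive_cox_de_boor(xi, k, p, t)
            if params.use_base:
                out[j] += params.base_weight[j, i] * x[i] / (1 + np.exp(-x[i]))
    return out


class TestSplineGrid:
    def test_knot_vector_structure(self):
        g = SplineGrid(intervals=5, degree=3)
        t = g.knots
        assert len(t) == 5 + 2 * 3 + 1
        assert np.all(np.diff(t) >= 0)
        assert np.all(t[:4] == -1) and np.all(t[-4:] == 1)
        assert g.n_basis == 8

    def test_degenerate_grids_rejected(self):
        with pytest.raises(ValueError):
            SplineGrid(lower=1, upper=-1)
        with pytest.raises(ValueError):
            SplineGrid(intervals=0)


class TestBsplineBasis:
    def test_degree0_indicator(self):
        g = SplineGrid(intervals=2, degree=0)
        assert np.array_equal(bspline_basis(-0.5, g), [1.0, 0.0])
        assert np.array_equal(bspline_basis(0.5, g), [0.0, 1.0])

    @pytest.mark.parametrize("p,G", [(0, 3), (1, 4), (2, 5), (3, 5), (4, 7)])
    def test_partition_of_unity(self, p, G, rng):
        """Basis values sum to 1 everywhere inside the domain."""
        g = SplineGrid(intervals=G, degree=p)
        x = rng.uniform(-1, 1, 10_000)
        assert np.abs(bspline_basis(x, g).sum(axis=-1) - 1).max() < 1e-10

    def test_matches_naive_recursion(self, rng):
        """Vectorized recursion equals the scalar textbook oracle."""
        g = SplineGrid(intervals=5, degree=3)
        t = g.knots
        xs = rng.uniform(-0.999, 0.999, 50)
        ours = bspline_basis(xs, g)
        theirs = np.array([[naive_cox_de_boor(x, k, 3, t)
                            for k in range(g.n_basis)] for x in xs])
        assert np.abs(ours - theirs).max() < 1e-12

    def test_matches_scipy_design_matrix(self, rng):
        import scipy.interpolate as si
        g = SplineGrid(intervals=7, degree=3)
        x = rng.uniform(-1, 1, 500)
        ref = si.BSpline.design_matrix(x, g.knots, g.degree).toarray()
        assert np.abs(bspline_basis(x, g) - ref).max() < 1e-12

    def test_out_of_range_clamped(self):
        g = SplineGrid()
        assert np.array_equal(bspline_basis(5.0, g), bspline_basis(1.0, g))
        assert np.array_equal(bspline_basis(-5.0, g), bspline_basis(-1.0, g))

    def test_derivative_matches_finite_difference(self, rng):
        g = SplineGrid()
        x = rng.uniform(-0.95, 0.95, 200)
        _, db = bspline_basis_and_deriv(x, g)
        eps = 1e-6
        fd = (bspline_basis(x + eps, g) - bspline_basis(x - eps, g)) / (2 * eps)
        assert np.abs(fd - db).max() < 1e-6


class TestKanLayerForward:
    def test_zero_coefficients_zero_output(self, rng):
        params = KanLayerParams(n_in=3, n_out=2, use_base=False)
        assert np.array_equal(kan_layer_forward(rng.normal(size=3), params),
                              np.zeros(2))

    def test_homogeneity_in_coefficients(self, rng):
        params = KanLayerParams(n_in=3, n_out=2,
                                coef=rng.normal(size=(2, 3, 8)), use_base=False)
        doubled = KanLayerParams(n_in=3, n_out=2, coef=2 * params.coef,
                                 use_base=False)
        x = rng.uniform(-1, 1, 3)
        assert np.allclose(kan_layer_forward(x, doubled),
                           2 * kan_layer_forward(x, params), atol=1e-14)

    def test_matches_brute_force_oracle(self, rng):
        """100 random layer configurations agree with the double-loop map."""
        for trial in range(100):
            n_in = int(rng.integers(1, 5))
            n_out = int(rng.integers(1, 4))
            g = SplineGrid(intervals=int(rng.integers(2, 7)),
                           degree=int(rng.integers(0, 4)))
            params = KanLayerParams(
                n_in=n_in, n_out=n_out, grid=g,
                coef=rng.normal(size=(n_out, n_in, g.n_basis)),
                base_weight=rng.normal(size=(n_out, n_in)),
                use_base=bool(rng.integers(0, 2)))
            x = rng.uniform(-1.2, 1.2, n_in)  # includes out-of-range values
            assert np.abs(kan_layer_forward(x, params)
                          - brute_force_layer(x, params)).max() < 1e-10

    def test_spline_interpolates_identity(self):
        """Cubic splines represent f(x) = x exactly; a least-squares fit of
        the coefficients must reproduce it to numerical precision."""
        g = SplineGrid()
        xs = np.linspace(-0.99, 0.99, 200)
        design = bspline_basis(xs, g)
        c, *_ = np.linalg.lstsq(design, xs, rcond=None)
        params = KanLayerParams(n_in=1, n_out=1, grid=g,
                                coef=c[None, None, :], use_base=False)
        fitted = np.array([kan_layer_forward(np.array([x]), params)[0]
                           for x in xs])
        assert np.abs(fitted - xs).max() < 1e-8

    def test_local_support_of_coefficients(self, rng):
        """Perturbing c[j,i,k] moves only output j, only where B_k > 0."""
        g = SplineGrid()
        base = KanLayerParams(n_in=2, n_out=2, grid=g,
                              coef=rng.normal(size=(2, 2, 8)), use_base=False)
        pert = KanLayerParams(n_in=2, n_out=2, grid=g,
                              coef=base.coef.copy(), use_base=False)
        j, i, k = 1, 0, 2
        pert.coef[j, i, k] += 1.0
        t = g.knots
        lo_k, hi_k = t[k], t[k + g.degree + 1]
        for x0 in np.linspace(-1, 1, 41):
            x = np.array([x0, 0.3])
            d = kan_layer_forward(x, pert) - kan_layer_forward(x, base)
            assert d[0] == 0.0  # other output untouched
            if not (lo_k <= x0 <= hi_k):
                assert abs(d[1]) < 1e-14

    def test_shape_mismatch_rejected(self, rng):
        params = KanLayerParams(n_in=3, n_out=2)
        with pytest.raises(ValueError, match="width"):
            kan_layer_forward(rng.normal(size=4), params)


class TestKanNetwork:
    def test_single_layer_equals_layer_forward(self, rng):
        params = KanLayerParams(n_in=3, n_out=2,
                                coef=rng.normal(size=(2, 3, 8)),
                                base_weight=rng.normal(size=(2, 3)))
        net = KanNetworkParams([params])
        x = rng.uniform(-1, 1, 3)
        assert np.array_equal(kan_forward(x, net), kan_layer_forward(x, params))

    def test_zero_layers_compose_to_zero(self):
        net = KanNetworkParams([KanLayerParams(n_in=3, n_out=4, use_base=False),
                                KanLayerParams(n_in=4, n_out=2, use_base=False)])
        assert np.array_equal(kan_forward(np.ones(3), net), np.zeros(2))

    def test_width_chain_enforced(self):
        with pytest.raises(ValueError, match="chain"):
            KanNetworkParams([KanLayerParams(n_in=3, n_out=4),
                              KanLayerParams(n_in=5, n_out=2)])

    def test_default_head_widths_give_scalar(self, rng):
        """[4, 32, 1] composes to a single output node."""
        net = KAN([4, 32, 1], np.random.default_rng(0), dtype=np.float64)
        out = kan_forward(rng.uniform(-1, 1, 4), net.export_params())
        assert out.shape == (1,)


class TestKanAutodiff:
    def test_module_matches_pure_function(self, rng):
        layer = KANLayer(4, 3, np.random.default_rng(2), dtype=np.float64)
        x = rng.uniform(-1.5, 1.5, (6, 4))
        got = layer(Tensor(x)).data
        want = kan_layer_forward(x, layer.export_params())
        assert np.abs(got - want).max() < 1e-10

    def test_gradients_match_finite_differences(self, rng):
        """Autodiff grads of a scalar loss agree with central differences
        to 1e-4 relative, for spline coefficients, base weights and inputs."""
        layer = KANLayer(3, 2, np.random.default_rng(3), dtype=np.float64)
        x = Tensor(rng.uniform(-0.9, 0.9, (4, 3)), requires_grad=True)
        loss = (layer(x) * layer(x)).sum()
        loss.backward()

        def loss_value():
            return float((kan_layer_forward(x.data, layer.export_params()) ** 2).sum())

        eps = 1e-6
        for tensor in (layer.coef, layer.base_weight, x):
            fd = np.zeros_like(tensor.data)
            for idx in np.ndindex(*tensor.data.shape):
                orig = tensor.data[idx]
                tensor.data[idx] = orig + eps
                fp = loss_value()
                tensor.data[idx] = orig - eps
                fm = loss_value()
                tensor.data[idx] = orig
                fd[idx] = (fp - fm) / (2 * eps)
            rel = np.abs(fd - tensor.grad).max() / max(np.abs(fd).max(), 1e-12)
            assert rel < 1e-4
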