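import numpy as np
import pytest
from scipy.interpolate import BSpline

from amfgnn._tensor import Tensor
from amfgnn.kan import (KanNetwork, MlpNetwork, SplineBasis, bspline_eval,
                        kan_activation)


def _silu(x):
    return x / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# B-spline basis
# --------------------------------------------------------------------------

def test_partition_of_unity_at_random_interior_points():
    basis = SplineBasis()
    rng = np.random.default_rng(0)
    x = rng.uniform(basis.lo, basis.hi, size=1000)
    b, _ = basis.design(x)
    np.testing.assert_allclose(b.sum(axis=-1), 1.0, atol=1e-6)
    assert (b >= 0).all()


def test_degree_zero_basis_is_interval_indicator():
    basis = SplineBasis(grid_intervals=4, order=0, lo=0.0, hi=4.0)
    for j, x in enumerate([0.5, 1.5, 2.5, 3.5]):
        vec = bspline_eval(basis, x)
        expected = np.zeros(4)
        expected[j] = 1.0
        np.testing.assert_array_equal(vec, expected)


def test_cubic_basis_matches_scipy_bspline():
    """Cross-check the Cox-de Boor recursion against scipy's B-splines."""
    basis = SplineBasis(grid_intervals=5, order=3, lo=-2.0, hi=2.0)
    x = np.linspace(-1.999, 1.999, 41)
    ours, _ = basis.design(x)
    for i in range(basis.n_basis):
        c = np.zeros(basis.n_basis)
        c[i] = 1.0
        ref = BSpline(basis.knots, c, basis.order, extrapolate=False)(x)
        np.testing.assert_allclose(ours[:, i], np.nan_to_num(ref), atol=1e-10)


def test_basis_derivative_matches_finite_differences():
    basis = SplineBasis()
    x = np.linspace(-1.9, 1.9, 23)
    _, db = basis.design(x)
    h = 1e-6
    bp, _ = basis.design(x + h)
    bm, _ = basis.design(x - h)
    np.testing.assert_allclose(db, (bp - bm) / (2 * h), atol=1e-6)


def test_out_of_range_clamps_to_endpoint_values():
    basis = SplineBasis()
    far, _ = basis.design(np.array([10.0]))
    edge, _ = basis.design(np.array([basis.hi]))
    np.testing.assert_allclose(far, edge)
    _, db = basis.design(np.array([10.0, -10.0]))
    np.testing.assert_array_equal(db, np.zeros_like(db))


def test_degenerate_grid_rejected():
    with pytest.raises(ValueError):
        SplineBasis(grid_intervals=0)
    with pytest.raises(ValueError):
        SplineBasis(lo=1.0, hi=1.0)


# --------------------------------------------------------------------------
# edge activation
# --------------------------------------------------------------------------

def test_activation_pure_silu_when_spline_weight_zero():
    basis = SplineBasis()
    coeffs = np.arange(basis.n_basis, dtype=float)
    assert kan_activation(2.0, 0.0, coeffs, basis, 0.0) == 0.0
    x = 0.7
    assert kan_activation(2.0, 0.0, coeffs, basis, x) == pytest.approx(
        2.0 * _silu(x)
    )


def test_activation_constant_spline_by_partition_of_unity():
    basis = SplineBasis()
    coeffs = np.full(basis.n_basis, 3.0)
    got = kan_activation(0.0, 2.0, coeffs, basis, 0.4)
    assert got == pytest.approx(6.0, abs=1e-9)


def test_activation_matches_scalar_formula_oracle(rng):
    basis = SplineBasis()
    for _ in range(10):
        w_b, w_s = rng.standard_normal(2)
        coeffs = rng.standard_normal(basis.n_basis)
        x = rng.uniform(-1.9, 1.9)
        expected = w_b * x / (1 + np.exp(-x)) + w_s * float(
            bspline_eval(basis, x) @ coeffs
        )
        got = kan_activation(w_b, w_s, coeffs, basis, x)
        assert got == pytest.approx(expected, rel=1e-12)


# --------------------------------------------------------------------------
# KAN network forward
# --------------------------------------------------------------------------

def _loop_oracle(net, z):
    """Nested-loop evaluation of x_{l+1,j} = sum_i phi_{l,j,i}(x_{l,i})."""
    x = np.asarray(z, dtype=float)
    for layer in net.layers:
        nxt = np.zeros(layer.n_out)
        for j in range(layer.n_out):
            for i in range(layer.n_in):
                nxt[j] += kan_activation(
                    layer.w_base.data[i, j], layer.w_spline.data[i, j],
                    layer.coeffs.data[i, j], layer.basis, x[i],
                )
        x = nxt
    return x


def test_single_activation_network_is_silu(rng):
    net = KanNetwork([1, 1], rng, normalize_input=False)
    net.layers[0].w_base.data[:] = 1.0
    net.layers[0].w_spline.data[:] = 0.0
    z = np.array([[0.63], [-1.2]])
    np.testing.assert_allclose(net.forward(Tensor(z)).data, _silu(z),
                               atol=1e-12)


def test_zeroed_activations_give_zero_output(rng):
    net = KanNetwork([2, 1], rng, normalize_input=False)
    net.layers[0].w_base.data[:] = 0.0
    net.layers[0].w_spline.data[:] = 0.0
    out = net.forward(Tensor(rng.standard_normal((5, 2)))).data
    np.testing.assert_array_equal(out, np.zeros((5, 1)))


def test_forward_matches_nested_loop_oracle(rng):
    net = KanNetwork([2, 2, 1], rng, normalize_input=False)
    for layer in net.layers:
        layer.coeffs.data = rng.standard_normal(layer.coeffs.shape)
        layer.w_base.data = rng.standard_normal(layer.w_base.shape)
        layer.w_spline.data = rng.standard_normal(layer.w_spline.shape)
    z = rng.uniform(-1.5, 1.5, size=(4, 2))
    got = net.forward(Tensor(z)).data
    for row in range(4):
        np.testing.assert_allclose(got[row], _loop_oracle(net, z[row]),
                                   atol=1e-10)


def test_forward_width_mismatch(rng):
    net = KanNetwork([2, 1], rng)
    with pytest.raises(ValueError):
        net.forward(Tensor(np.zeros((3, 3))))


def test_forward_continuity_under_small_perturbation(rng):
    net = KanNetwork([3, 2], rng, normalize_input=False)
    z = rng.uniform(-1.5, 1.5, size=(1, 3))
    base = net.forward(Tensor(z)).data
    for delta in (1e-3, 1e-5):
        moved = net.forward(Tensor(z + delta)).data
        assert np.abs(moved - base).max() < 100 * delta


def test_kan_parameter_gradients_match_finite_differences(rng):
    net = KanNetwork([2, 2, 1], rng, normalize_input=False)
    z = Tensor(rng.uniform(-1.5, 1.5, size=(5, 2)))

    def loss_value():
        out = net.forward(z)
        return (out * out).sum()

    loss_value().backward()
    h = 1e-6
    for p in net.parameters():
        flat_choices = np.unravel_index(
            np.random.default_rng(0).integers(0, p.data.size, size=3),
            p.data.shape,
        )
        for idx in zip(*[np.atleast_1d(a) for a in flat_choices]):
            old = p.data[idx]
            p.data[idx] = old + h
            lp = loss_value().item()
            p.data[idx] = old - h
            lm = loss_value().item()
            p.data[idx] = old
            fd = (lp - lm) / (2 * h)
            assert p.grad[idx] == pytest.approx(fd, abs=1e-4), p


# --------------------------------------------------------------------------
# MLP ablation head
# --------------------------------------------------------------------------

def test_mlp_identity_single_layer(rng):
    net = MlpNetwork([3, 3], rng)
    net.weights[0].data = np.eye(3)
    net.biases[0].data = np.zeros(3)
    z = np.abs(rng.standard_normal((2, 3)))
    np.testing.assert_allclose(net.forward(Tensor(z)).data, z)


def test_mlp_zero_weights_zero_logits(rng):
    net = MlpNetwork([4, 2, 1], rng)
    for w in net.weights:
        w.data[:] = 0.0
    out = net.forward(Tensor(rng.standard_normal((3, 4)))).data
    np.testing.assert_array_equal(out, np.zeros((3, 1)))


def test_mlp_two_layer_matches_matrix_oracle(rng):
    net = MlpNetwork([2, 2, 1], rng)
    z = rng.standard_normal((3, 2))
    expected = _silu(z @ net.weights[0].data + net.biases[0].data)
    expected = expected @ net.weights[1].data + net.biases[1].data
    np.testing.assert_allclose(net.forward(Tensor(z)).data, expected,
                               atol=1e-12)
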