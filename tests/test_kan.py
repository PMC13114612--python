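"""KAN head: B-spline basis against an independent oracle, partition of
unity, edge activations, grid refresh and curve extraction."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from dfcmamba.autodiff import Tensor
from dfcmamba.kan import (
    ActivationCurve,
    KANClassifier,
    KANLayer,
    SplineGrid,
    bspline_basis,
    bspline_basis_derivative,
    edge_activation,
)


def scipy_basis(x, grid: SplineGrid) -> np.ndarray:
    """Independent oracle: each basis function via scipy's basis_element
    (valid on its own knot support, zero elsewhere — the same convention as
    the Cox-de Boor recursion over the extended knot vector)."""
    knots = grid.knots
    p = grid.order
    x = np.asarray(x, dtype=float)
    out = np.zeros(np.shape(x) + (grid.n_basis,))
    for i in range(grid.n_basis):
        spl = BSpline.basis_element(knots[i : i + p + 2], extrapolate=False)
        vals = np.nan_to_num(spl(x))
        vals[x == knots[i + p + 1]] = 0.0  # right-open support
        out[..., i] = vals
    return out


class TestBasis:
    def test_count_is_g_plus_p(self):
        grid = SplineGrid(n_intervals=5, order=3)
        assert grid.n_basis == 8
        assert bspline_basis(0.3, grid).shape == (8,)
        assert len(grid.knots) == 5 + 2 * 3 + 1

    def test_partition_of_unity_inside_domain(self):
        grid = SplineGrid(-1.0, 1.0, 5, 3)
        xs = np.linspace(-1.0, 1.0, 100)
        sums = bspline_basis(xs, grid).sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-10)
        assert np.all(bspline_basis(xs, grid) >= 0)

    def test_matches_scipy_cox_de_boor(self):
        grid = SplineGrid(-2.0, 3.0, 7, 3)
        xs = np.linspace(-2.0, 3.0, 20, endpoint=False) + 0.01
        ours = bspline_basis(xs, grid)
        oracle = scipy_basis(xs, grid)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_derivative_matches_finite_differences(self):
        grid = SplineGrid(-1.0, 1.0, 5, 3)
        xs = np.linspace(-0.95, 0.95, 17)
        eps = 1e-6
        num = (bspline_basis(xs + eps, grid) - bspline_basis(xs - eps, grid)) / (2 * eps)
        assert np.allclose(bspline_basis_derivative(xs, grid), num, atol=1e-6)

    def test_decays_outside_support(self):
        grid = SplineGrid(-1.0, 1.0, 5, 3)
        assert np.allclose(bspline_basis(np.array([-5.0, 5.0]), grid), 0.0)


class TestEdgeActivation:
    def test_spline_off_reduces_to_silu(self):
        grid = SplineGrid()
        xs = np.linspace(-2, 2, 9)
        phi = edge_activation(xs, 1.0, np.zeros(grid.n_basis), grid)
        assert np.allclose(phi, xs / (1 + np.exp(-xs)))
        assert edge_activation(0.0, 1.0, np.zeros(grid.n_basis), grid) == 0.0

    def test_unit_coefficients_give_one_inside_domain(self):
        grid = SplineGrid(-1, 1, 5, 3)
        xs = np.linspace(-1, 1, 11)
        phi = edge_activation(xs, 0.0, np.ones(grid.n_basis), grid)
        assert np.allclose(phi, 1.0, atol=1e-10)

    def test_random_coefficients_against_scipy(self):
        rng = np.random.default_rng(0)
        grid = SplineGrid(-1, 1, 5, 3)
        coeffs = rng.standard_normal(grid.n_basis)
        xs = rng.uniform(-1, 1, 15)
        expect = scipy_basis(xs, grid) @ coeffs + 0.7 * xs / (1 + np.exp(-xs))
        assert np.allclose(edge_activation(xs, 0.7, coeffs, grid), expect, atol=1e-10)


class TestKANLayer:
    def test_single_edge_reduces_to_edge_activation(self):
        layer = KANLayer(1, 1, np.random.default_rng(0))
        x = np.array([0.37])
        out = layer(x).data
        expect = edge_activation(0.37, layer.base_weight.data[0, 0],
                                 layer.spline_coeff.data[0, 0], layer.grid)
        assert out[0] == pytest.approx(expect)

    def test_spline_off_additive_silu_model(self):
        layer = KANLayer(2, 1, np.random.default_rng(1))
        layer.spline_coeff.data[:] = 0.0
        layer.base_weight.data[:] = np.array([[2.0, -1.0]])
        x = np.array([0.5, -0.3])
        silu = x / (1 + np.exp(-x))
        assert layer(x).data[0] == pytest.approx(2 * silu[0] - silu[1])

    def test_dead_edge_has_no_influence(self):
        rng = np.random.default_rng(2)
        layer = KANLayer(3, 2, rng)
        layer.base_weight.data[:, 1] = 0.0
        layer.spline_coeff.data[:, 1, :] = 0.0
        x1 = np.array([0.1, -0.5, 0.9])
        x2 = np.array([0.1, 5.0, 0.9])
        assert np.allclose(layer(x1).data, layer(x2).data)

    def test_dimension_check(self):
        layer = KANLayer(3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer(np.zeros(4))

    def test_gradient_through_basis(self):
        layer = KANLayer(2, 2, np.random.default_rng(3))
        x = Tensor(np.array([0.2, -0.4]), requires_grad=True)
        layer(x).sum().backward()
        eps = 1e-6
        for i in range(2):
            x.data[i] += eps
            f1 = layer(Tensor(x.data)).sum().item()
            x.data[i] -= 2 * eps
            f0 = layer(Tensor(x.data)).sum().item()
            x.data[i] += eps
            assert x.grad[i] == pytest.approx((f1 - f0) / (2 * eps), abs=1e-5)


class TestGridUpdate:
    def test_refit_preserves_function_on_old_domain(self):
        rng = np.random.default_rng(4)
        layer = KANLayer(2, 2, rng)
        old_grid = layer.grid
        probes = np.linspace(old_grid.x_min, old_grid.x_max, 50)
        before = np.stack([[edge_activation(probes, layer.base_weight.data[j, i],
                                            layer.spline_coeff.data[j, i], layer.grid)
                            for i in range(2)] for j in range(2)])
        layer.update_grid(np.array([-2.0, 2.0]))  # domain doubled
        after = np.stack([[edge_activation(probes, layer.base_weight.data[j, i],
                                           layer.spline_coeff.data[j, i], layer.grid)
                           for i in range(2)] for j in range(2)])
        # halving the knot density cannot represent the old spline exactly;
        # the refit must stay close relative to the curve scale and must be
        # the least-squares optimum over the new basis
        scale = max(1.0, np.abs(before).max())
        assert np.abs(after - before).max() / scale < 0.1
        assert layer.grid.x_min < old_grid.x_min
        # independent optimality check on one edge: the refit is the
        # least-squares projection of the old spline onto the new basis,
        # probed over the new domain (the old spline is 0 outside its span)
        fresh = KANLayer(1, 1, np.random.default_rng(0), grid=SplineGrid(**vars(old_grid)))
        coeffs = np.linspace(-1, 1, old_grid.n_basis)
        fresh.spline_coeff.data[0, 0] = coeffs
        fresh.update_grid(np.array([-2.0, 2.0]), n_probe=200)
        dense = np.linspace(fresh.grid.x_min, fresh.grid.x_max, 200)
        target = scipy_basis(dense, old_grid) @ coeffs
        design = scipy_basis(dense, fresh.grid)
        opt_coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        ours = design @ fresh.spline_coeff.data[0, 0]
        assert np.abs(ours - design @ opt_coef).max() < 5e-3

    def test_same_range_is_noop_within_tolerance(self):
        rng = np.random.default_rng(5)
        layer = KANLayer(1, 1, rng)
        xs = np.linspace(-0.99, 0.99, 30)
        before = edge_activation(xs, layer.base_weight.data[0, 0],
                                 layer.spline_coeff.data[0, 0], layer.grid)
        layer.update_grid(np.array([-1.0, 1.0]), margin=0.0)
        after = edge_activation(xs, layer.base_weight.data[0, 0],
                                layer.spline_coeff.data[0, 0], layer.grid)
        assert np.abs(after - before).max() < 1e-3

    def test_degenerate_range_warns_and_keeps_grid(self):
        layer = KANLayer(1, 1, np.random.default_rng(6))
        grid_before = layer.grid
        with pytest.warns(UserWarning, match="degenerate"):
            layer.update_grid(np.full(10, 0.5))
        assert layer.grid is grid_before


class TestClassifier:
    def test_softmax_simplex(self):
        clf = KANClassifier(6, 4, 4, np.random.default_rng(0))
        logits = clf(np.random.default_rng(1).standard_normal(6))
        probs = logits.softmax().data
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(probs > 0)

    def test_equal_logits_uniform(self):
        clf = KANClassifier(3, 2, 4, np.random.default_rng(0))
        assert np.allclose(Tensor(np.zeros(4)).softmax().data, 0.25)

    def test_deterministic(self):
        clf = KANClassifier(5, 3, 2, np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal(5)
        assert np.array_equal(clf(x).data, clf(x).data)

    def test_extract_curve_flags(self):
        clf = KANClassifier(2, 2, 2, np.random.default_rng(1))
        layer = clf.layer1
        # pruned edge -> flat ~0 curve
        layer.base_weight.data[0, 0] = 0.0
        layer.spline_coeff.data[0, 0, :] = 0.0
        curve = clf.extract_curve(1, 0, 0)
        assert np.allclose(curve.phi, 0.0)
        assert curve.monotonic == "flat"
        # spline-off SiLU edge sampled correctly
        layer.base_weight.data[1, 1] = 1.0
        layer.spline_coeff.data[1, 1, :] = 0.0
        curve2 = clf.extract_curve(1, 1, 1)
        assert np.allclose(curve2.phi, curve2.x / (1 + np.exp(-curve2.x)))
        # hand-built increasing spline reported as increasing
        layer.base_weight.data[0, 1] = 1.0
        layer.spline_coeff.data[0, 1, :] = np.linspace(-1, 1, layer.grid.n_basis)
        assert clf.extract_curve(1, 0, 1).monotonic == "increasing"

    def test_bad_indices_rejected(self):
        clf = KANClassifier(2, 2, 2, np.random.default_rng(1))
        with pytest.raises(IndexError):
            clf.extract_curve(3, 0, 0)
        with pytest.raises(IndexError):
            clf.extract_curve(1, 5, 0)
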