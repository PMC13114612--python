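"""Kolmogorov-Arnold classification head with B-spline edge activations.

Instead of fixed node nonlinearities, every edge (i -> j) of a KAN layer
carries its own learnable univariate function

    phi(x) = w_b * SiLU(x) + sum_m c_m * B_{m,p}(x),

a scaled SiLU base term plus a cubic B-spline with ``G + p`` coefficients on
a uniform grid of ``G`` intervals (default G=5, p=3, hence 8 basis functions
per edge).  Layer outputs are plain sums of edge activations, so the learned
curves can be read directly off the parameters — the head is interpretable
by construction.  The grid is periodically refreshed to span the current
activation range, with coefficients refitted by least squares so the learned
function is preserved.

Basis evaluation uses the Cox-de Boor recursion; outside the knot span the
basis decays to zero and the SiLU term keeps gradients alive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module

__all__ = [
    "SplineGrid",
    "bspline_basis",
    "bspline_basis_derivative",
    "edge_activation",
    "KANLayer",
    "KANClassifier",
    "ActivationCurve",
]


@dataclass
class SplineGrid:
    """Uniform extended knot grid: G intervals, order p, G+p basis functions."""

    x_min: float = -1.0
    x_max: float = 1.0
    n_intervals: int = 5
    order: int = 3

    def __post_init__(self):
        if self.x_min >= self.x_max:
            raise ValueError("x_min must be < x_max")
        if self.n_intervals < 1 or self.order < 1:
            raise ValueError("n_intervals and order must be positive")

    @property
    def n_basis(self) -> int:
        return self.n_intervals + self.order

    @property
    def knots(self) -> np.ndarray:
        """G + 2p + 1 uniformly spaced knots, p extra on each side."""
        g, p = self.n_intervals, self.order
        h = (self.x_max - self.x_min) / g
        return self.x_min + h * np.arange(-p, g + p + 1)


def _cox_de_boor_all(x: np.ndarray, knots: np.ndarray, order: int) -> list[np.ndarray]:
    """All basis orders 0..p at points x; returns a list indexed by degree.

    Degree-0 functions are interval indicators, half-open except that the
    right domain endpoint is folded into the last interior interval so the
    partition of unity holds on the closed domain.
    """
    x = np.asarray(x, dtype=np.float64)
    n0 = len(knots) - 1
    b = np.zeros(x.shape + (n0,))
    for i in range(n0):
        b[..., i] = (knots[i] <= x) & (x < knots[i + 1])
    # fold the closed right endpoint of the interior domain
    right = x == knots[-(order + 1)]
    if np.any(right):
        b[right] = 0.0
        b[..., n0 - order - 1][right] = 1.0
    levels = [b]
    for d in range(1, order + 1):
        prev = levels[-1]
        n = n0 - d
        cur = np.zeros(x.shape + (n,))
        for i in range(n):
            left_den = knots[i + d] - knots[i]
            right_den = knots[i + d + 1] - knots[i + 1]
            term = 0.0
            if left_den > 0:
                term = (x - knots[i]) / left_den * prev[..., i]
            if right_den > 0:
                term = term + (knots[i + d + 1] - x) / right_den * prev[..., i + 1]
            cur[..., i] = term
        levels.append(cur)
    return levels


def bspline_basis(x: np.ndarray | float, grid: SplineGrid) -> np.ndarray:
    """Values of all G+p basis functions at x (appended as a last axis)."""
    return _cox_de_boor_all(np.asarray(x, dtype=np.float64), grid.knots, grid.order)[-1]


def bspline_basis_derivative(x: np.ndarray | float, grid: SplineGrid) -> np.ndarray:
    """d/dx of every basis function: p * (B_{i,p-1}/den_i - B_{i+1,p-1}/den_{i+1})."""
    knots, p = grid.knots, grid.order
    levels = _cox_de_boor_all(np.asarray(x, dtype=np.float64), knots, p)
    lower = levels[p - 1]
    n = grid.n_basis
    out = np.zeros(lower.shape[:-1] + (n,))
    for i in range(n):
        den1 = knots[i + p] - knots[i]
        den2 = knots[i + p + 1] - knots[i + 1]
        term = 0.0
        if den1 > 0:
            term = p * lower[..., i] / den1
        if den2 > 0:
            term = term - p * lower[..., i + 1] / den2
        out[..., i] = term
    return out


def _basis_features(x: Tensor, grid: SplineGrid) -> Tensor:
    """Differentiable basis evaluation (custom vector-Jacobian product)."""
    vals = bspline_basis(x.data, grid)

    def backward():
        if x.requires_grad:
            dvals = bspline_basis_derivative(x.data, grid)
            x._accum((out.grad * dvals).sum(axis=-1))

    out = Tensor._make(vals, (x,), backward)
    return out


def edge_activation(x, w_b: float, coeffs: np.ndarray, grid: SplineGrid):
    """phi(x) = w_b * SiLU(x) + sum_m c_m B_m(x), for scalar or array x."""
    x = np.asarray(x, dtype=np.float64)
    silu = x / (1.0 + np.exp(-x))
    return w_b * silu + bspline_basis(x, grid) @ np.asarray(coeffs, dtype=np.float64)


class KANLayer(Module):
    """One KAN layer: n_out x n_in independent edge activations, summed per node."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 grid: SplineGrid | None = None, coeff_sd: float = 0.1):
        self.n_in, self.n_out = n_in, n_out
        self.grid = grid or SplineGrid()
        self.base_weight = Tensor(np.ones((n_out, n_in)), requires_grad=True)
        self.spline_coeff = Tensor(
            rng.normal(0.0, coeff_sd, size=(n_out, n_in, self.grid.n_basis)),
            requires_grad=True,
        )

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.shape[-1] != self.n_in:
            raise ValueError(f"input width {x.shape[-1]} != n_in={self.n_in}")
        basis = _basis_features(x, self.grid)  # (..., n_in, n_basis)
        flat = basis.reshape(x.shape[:-1] + (self.n_in * self.grid.n_basis,))
        c_flat = self.spline_coeff.reshape((self.n_out, self.n_in * self.grid.n_basis))
        spline_term = flat @ c_flat.transpose()
        base_term = x.silu() @ self.base_weight.transpose()
        return base_term + spline_term

    # -- grid refresh ------------------------------------------------------
    def update_grid(self, activations: np.ndarray, margin: float = 0.01,
                    n_probe: int = 200) -> None:
        """Re-span the grid to the observed activation range and refit the
        spline coefficients by least squares so phi is preserved on the old
        domain (max abs gap below ~1e-3 for in-range activations)."""
        activations = np.asarray(activations, dtype=np.float64).ravel()
        if activations.size == 0:
            raise ValueError("empty activation sample")
        lo, hi = float(activations.min()), float(activations.max())
        if lo == hi:
            warnings.warn("degenerate activation range; grid not updated", stacklevel=2)
            return
        span = hi - lo
        new_grid = SplineGrid(lo - margin * span, hi + margin * span,
                              self.grid.n_intervals, self.grid.order)
        # probe the NEW domain: probing only the old one leaves the new
        # basis rank-deficient when the domain grows and the least-squares
        # coefficients explode (the old spline is 0 outside its knot span,
        # which is also the correct extension target)
        probes = np.linspace(new_grid.x_min, new_grid.x_max, n_probe)
        old_vals = bspline_basis(probes, self.grid) @ np.moveaxis(self.spline_coeff.data, -1, 0).reshape(self.grid.n_basis, -1)
        design = bspline_basis(probes, new_grid)
        coef, *_ = np.linalg.lstsq(design, old_vals, rcond=None)
        self.spline_coeff.data = np.moveaxis(
            coef.reshape(new_grid.n_basis, self.n_out, self.n_in), 0, -1
        ).copy()
        self.grid = new_grid


@dataclass
class ActivationCurve:
    """A sampled edge function phi_{j,i}, read straight off the parameters."""

    layer: int
    j: int
    i: int
    x: np.ndarray
    phi: np.ndarray
    influence: float = float("nan")

    @property
    def monotonic(self) -> str:
        """'increasing', 'decreasing', 'flat' or 'non-monotonic' (finite diff)."""
        d = np.diff(self.phi)
        tol = 1e-9 * max(1.0, np.abs(self.phi).max())
        if np.all(np.abs(d) <= tol):
            return "flat"
        if np.all(d >= -tol):
            return "increasing"
        if np.all(d <= tol):
            return "decreasing"
        return "non-monotonic"


class KANClassifier(Module):
    """Two-layer KAN head: context -> hidden -> class logits."""

    def __init__(self, n_in: int, n_hidden: int, n_classes: int,
                 rng: np.random.Generator, grid: SplineGrid | None = None):
        grid = grid or SplineGrid()
        self.layer1 = KANLayer(n_in, n_hidden, rng, grid=SplineGrid(**vars(grid)))
        self.layer2 = KANLayer(n_hidden, n_classes, rng, grid=SplineGrid(**vars(grid)))
        self.n_classes = n_classes

    def __call__(self, c: Tensor | np.ndarray) -> Tensor:
        """Class logits (apply ``.softmax()`` for probabilities)."""
        return self.layer2(self.layer1(c))

    def hidden(self, c: Tensor | np.ndarray) -> Tensor:
        return self.layer1(c)

    def extract_curve(self, layer: int, j: int, i: int, n_points: int = 100) -> ActivationCurve:
        """Sample phi_{j,i} of the given layer over its grid domain."""
        lyr = {1: self.layer1, 2: self.layer2}.get(layer)
        if lyr is None:
            raise IndexError(f"layer must be 1 or 2, got {layer}")
        if not (0 <= j < lyr.n_out and 0 <= i < lyr.n_in):
            raise IndexError(f"edge ({j},{i}) out of range for layer {layer}")
        xs = np.linspace(lyr.grid.x_min, lyr.grid.x_max, n_points)
        phi = edge_activation(xs, lyr.base_weight.data[j, i],
                              lyr.spline_coeff.data[j, i], lyr.grid)
        return ActivationCurve(layer=layer, j=j, i=i, x=xs, phi=phi)
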