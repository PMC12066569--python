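"""Kolmogorov-Arnold network layers with learnable B-spline activations.

Every edge (l, i, j) of the network carries its own univariate activation

    phi(x) = w_b * SiLU(x) + w_s * sum_i c_i B_i(x),

where B_i are B-spline basis functions on a fixed grid (default: 5
intervals, degree 3, range [-2, 2]).  Node values are the sums of incoming
post-activations, x_{l+1,j} = sum_i phi_{l,j,i}(x_{l,i}).  Inputs to each
layer are rescaled by a non-learned layer-norm so they land in the grid
range; values still outside are clamped to the range endpoints (where the
spline gradient is zero).  Spline coefficients start near zero with
w_b = w_s = 1, so the network begins close to a SiLU MLP without mixing
weights.

The basis is evaluated by the Cox-de Boor recursion on a uniformly extended
knot vector; its derivative (needed for backpropagation through the input)
uses the standard degree-lowering formula.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter, Tensor

__all__ = ["SplineBasis", "bspline_eval", "KanLayer", "KanNetwork",
           "MlpNetwork", "kan_activation"]


class SplineBasis:
    """B-spline basis on a bounded interval.

    grid_intervals uniform intervals on [lo, hi], degree ``order``; the knot
    vector is extended uniformly beyond both ends so that n_basis =
    grid_intervals + order functions form a partition of unity on [lo, hi].
    """

    def __init__(self, grid_intervals: int = 5, order: int = 3,
                 lo: float = -2.0, hi: float = 2.0):
        if grid_intervals < 1 or order < 0 or not hi > lo:
            raise ValueError("degenerate spline grid")
        self.order = order
        self.lo, self.hi = float(lo), float(hi)
        self.grid_intervals = grid_intervals
        h = (hi - lo) / grid_intervals
        self.knots = lo + h * np.arange(-order, grid_intervals + order + 1)
        self.n_basis = grid_intervals + order

    def _clamp(self, x: np.ndarray) -> np.ndarray:
        # keep strictly below hi so the half-open degree-0 intervals cover it
        span = self.hi - self.lo
        return np.clip(x, self.lo, self.hi - 1e-12 * span)

    def design(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Basis values and derivatives at x (any shape).

        Returns (B, dB) each of shape x.shape + (n_basis,).  dB is the
        derivative with respect to x; it is zero where x was clamped.
        """
        t = self.knots
        xc = self._clamp(np.asarray(x, dtype=float))
        inside = (np.asarray(x) >= self.lo) & (np.asarray(x) <= self.hi)
        xe = xc[..., None]
        # degree 0: indicators on the half-open knot intervals
        b = ((xe >= t[:-1]) & (xe < t[1:])).astype(float)
        b_prev = None
        for k in range(1, self.order + 1):
            b_prev = b
            left = (xe - t[: -(k + 1)]) / (t[k:-1] - t[: -(k + 1)])
            right = (t[k + 1:] - xe) / (t[k + 1:] - t[1:-k])
            b = left * b[..., :-1] + right * b[..., 1:]
        if self.order == 0:
            db = np.zeros_like(b)
        else:
            k = self.order
            inv1 = k / (t[k:-1] - t[: -(k + 1)])
            inv2 = k / (t[k + 1:] - t[1:-k])
            db = inv1 * b_prev[..., :-1] - inv2 * b_prev[..., 1:]
        db = db * inside[..., None]
        return b, db


def bspline_eval(basis: SplineBasis, x: float) -> np.ndarray:
    """Vector of basis values B_i(x); out-of-range x is clamped."""
    b, _ = basis.design(np.asarray(x, dtype=float))
    return b


def _bspline_tensor(x: Tensor, basis: SplineBasis) -> Tensor:
    """Autodiff node: basis design matrix of x, differentiable in x."""
    b, db = basis.design(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum((g * db).sum(axis=-1))

    return Tensor._make(b, (x,), backward)


def kan_activation(w_b: float, w_s: float, coeffs: np.ndarray,
                   basis: SplineBasis, x: float) -> float:
    """Single-edge activation phi(x) = w_b*SiLU(x) + w_s*sum c_i B_i(x)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (basis.n_basis,):
        raise ValueError(
            f"need {basis.n_basis} coefficients, got {coeffs.shape}"
        )
    silu = x / (1.0 + np.exp(-x))
    return float(w_b * silu + w_s * bspline_eval(basis, x) @ coeffs)


def _layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row standardisation (no learned gain/shift)."""
    m = x.mean(axis=1, keepdims=True)
    c = x - m
    v = (c * c).mean(axis=1, keepdims=True)
    return c / (v + eps).sqrt()


class KanLayer:
    """n_in x n_out learnable edge activations, summed into output nodes.

    Base weights start fan-in-scaled random (equal base weights would make
    every output unit the same function at init, collapsing the layer's
    effective width); spline weights start at 1 with near-zero
    coefficients, so each edge begins close to a scaled SiLU.
    """

    def __init__(self, n_in: int, n_out: int, basis: SplineBasis,
                 rng: np.random.Generator, coeff_scale: float = 0.1):
        self.n_in, self.n_out = n_in, n_out
        self.basis = basis
        limit = np.sqrt(3.0 / n_in)
        self.w_base = Parameter(rng.uniform(-limit, limit, (n_in, n_out)))
        self.w_spline = Parameter(np.full((n_in, n_out), 1.0))
        self.coeffs = Parameter(
            coeff_scale * rng.standard_normal((n_in, n_out, basis.n_basis))
            / np.sqrt(n_in)
        )

    def parameters(self) -> list:
        return [self.w_base, self.w_spline, self.coeffs]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.n_in:
            raise ValueError(
                f"input width {x.shape[1]} does not match layer width "
                f"{self.n_in}"
            )
        nb = self.basis.n_basis
        base = x.silu() @ self.w_base
        b = _bspline_tensor(x, self.basis)                 # (N, n_in, nb)
        eff = self.w_spline.reshape(self.n_in, self.n_out, 1) * self.coeffs
        eff = eff.transpose(0, 2, 1).reshape(self.n_in * nb, self.n_out)
        spline = b.reshape(x.shape[0], self.n_in * nb) @ eff
        return base + spline


class KanNetwork:
    """Stacked KAN layers, widths [n_0, ..., n_L]."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 basis: SplineBasis | None = None,
                 normalize_input: bool = True):
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = list(widths)
        self.basis = basis or SplineBasis()
        self.normalize_input = normalize_input
        self.layers = [
            KanLayer(a, b, self.basis, rng)
            for a, b in zip(widths[:-1], widths[1:])
        ]
        for layer in self.layers:
            layer.w_spline.data /= np.sqrt(layer.n_in)

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, z: Tensor) -> Tensor:
        if z.shape[1] != self.widths[0]:
            raise ValueError(
                f"input width {z.shape[1]} != n_0 = {self.widths[0]}"
            )
        if self.normalize_input:
            z = _layer_norm(z)
        for layer in self.layers:
            z = layer.forward(z)
        return z


class MlpNetwork:
    """Affine + SiLU stack with the same widths interface (ablation head)."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = list(widths)
        self.weights, self.biases = [], []
        for a, b in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (a + b))
            self.weights.append(Parameter(rng.uniform(-limit, limit, (a, b))))
            self.biases.append(Parameter(np.zeros(b)))

    def parameters(self) -> list:
        return [*self.weights, *self.biases]

    def forward(self, z: Tensor) -> Tensor:
        if z.shape[1] != self.widths[0]:
            raise ValueError(
                f"input width {z.shape[1]} != n_0 = {self.widths[0]}"
            )
        last = len(self.weights) - 1
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = z @ W + b
            if li != last:
                z = z.silu()
        return z
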