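"""Adaptive multi-view fusion.

Each entity carries two views: the similarity-graph GAT embedding H^(1) and
the association-graph GAT embedding H^(2).  To counter over-smoothing, the
last-layer GAT output of each view is mixed with a residual transform of the
view's initial features,

    H^(view) = eps * H^l + (1 - eps) * Elu(W h0 + b),

and the two views are fused by a learned convex combination concatenated
with both views,

    H = [eta * H^(1) + (1 - eta) * H^(2) ; H^(1) ; H^(2)],

so the fused width is three times the view width.  The mixing scalars eps
and eta are sigmoids of unconstrained parameters (initialised at 0, i.e.
an unbiased 0.5/0.5 mix) and therefore stay strictly inside (0, 1).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter, Tensor, concat

__all__ = ["ResidualTransform", "AdaptiveScalar", "residual_mix", "fuse_views"]


class ResidualTransform:
    """Elu(W h0 + b) applied to a view's initial feature representation."""

    def __init__(self, width: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (2 * width))
        self.weight = Parameter(rng.uniform(-limit, limit, (width, width)))
        self.bias = Parameter(np.zeros(width))

    def parameters(self) -> list:
        return [self.weight, self.bias]

    def forward(self, h0: Tensor) -> Tensor:
        if h0.shape[1] != self.weight.shape[0]:
            raise ValueError(
                f"width {h0.shape[1]} does not match residual map "
                f"{self.weight.shape}"
            )
        return (h0 @ self.weight + self.bias).elu()


class AdaptiveScalar:
    """A scalar in (0,1): sigmoid of a trainable unconstrained parameter."""

    def __init__(self, init_logit: float = 0.0):
        self.logit = Parameter(np.array(init_logit))

    def parameters(self) -> list:
        return [self.logit]

    @property
    def value(self) -> Tensor:
        return self.logit.sigmoid()


def residual_mix(last_layer: Tensor, residual: Tensor, eps) -> Tensor:
    """eps * H^l + (1 - eps) * R, elementwise (eps scalar in (0,1))."""
    if last_layer.shape != residual.shape:
        raise ValueError(
            f"shape mismatch {last_layer.shape} vs {residual.shape}"
        )
    eps = Tensor.as_tensor(eps)
    return eps * last_layer + (1.0 - eps) * residual


def fuse_views(v1: Tensor, v2: Tensor, eta) -> Tensor:
    """[eta*v1 + (1-eta)*v2 ; v1 ; v2] along the feature axis (width x3)."""
    if v1.shape != v2.shape:
        raise ValueError(f"shape mismatch {v1.shape} vs {v2.shape}")
    eta = Tensor.as_tensor(eta)
    mix = eta * v1 + (1.0 - eta) * v2
    return concat([mix, v1, v2], axis=1)
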