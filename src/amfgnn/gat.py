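"""Multi-head graph attention encoder.

A three-layer twin design: the drug and disease similarity graphs are
encoded by stacks with identical architecture but separate weights, and a
third stack encodes the bipartite association graph.  Attention over the
neighbourhood of node i is

    alpha_ij = softmax_{j in Ne(i)} LeakyReLU(a . [W h_i || W h_j])

with a learnable per-head score vector ``a`` split into its source and
destination halves (so the score decomposes as a_src.Wh_i + a_dst.Wh_j).
Hidden layers concatenate head outputs; the final layer averages them.
The per-head aggregation nonlinearity is LeakyReLU.  Dropout acts on layer
inputs and on attention coefficients during training only.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter, Tensor, concat

__all__ = ["GatLayer", "GatStack", "attention_coefficients"]


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


class GatLayer:
    """One multi-head graph-attention layer.

    Parameters per head k: weight W^k (f_in x f_out) and attention score
    vector a^k of length 2*f_out.  ``mode='concat'`` returns width
    n_heads*f_out, ``mode='average'`` the per-head mean of width f_out.
    """

    def __init__(self, f_in: int, f_out: int, n_heads: int,
                 rng: np.random.Generator, negative_slope: float = 0.2,
                 dropout_rate: float = 0.2):
        if n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if negative_slope <= 0:
            raise ValueError("negative_slope must be > 0")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.f_in, self.f_out, self.n_heads = f_in, f_out, n_heads
        self.negative_slope = negative_slope
        self.dropout_rate = dropout_rate
        self.weights = [Parameter(_glorot(rng, (f_in, f_out)))
                        for _ in range(n_heads)]
        self.attn_vectors = [Parameter(_glorot(rng, (2 * f_out,)))
                             for _ in range(n_heads)]

    def parameters(self) -> list:
        return [*self.weights, *self.attn_vectors]

    def _dropout(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None) -> Tensor:
        if not training or self.dropout_rate == 0.0 or rng is None:
            return x
        keep = 1.0 - self.dropout_rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)

    def head_attention(self, head: int, adjacency: np.ndarray,
                       h: Tensor) -> Tensor:
        """Dense n x n attention matrix for one head (rows sum to 1 on the
        neighbourhood support; zero off-support)."""
        W, a = self.weights[head], self.attn_vectors[head]
        s = h @ W
        a_src = a[: self.f_out].reshape(1, self.f_out)
        a_dst = a[self.f_out:].reshape(1, self.f_out)
        src = (s * a_src).sum(axis=1, keepdims=True)       # (n, 1)
        dst = (s * a_dst).sum(axis=1, keepdims=True)       # (n, 1)
        e = (src + dst.T).leaky_relu(self.negative_slope)  # e_ij
        return e.softmax_masked(adjacency.astype(bool))

    def forward(self, adjacency: np.ndarray, h: Tensor, mode: str = "concat",
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if h.shape[1] != self.f_in:
            raise ValueError(
                f"feature width {h.shape[1]} does not match layer input "
                f"width {self.f_in}"
            )
        if mode not in ("concat", "average"):
            raise ValueError(f"unknown mode {mode!r}")
        h = self._dropout(h, training, rng)
        outs = []
        for k in range(self.n_heads):
            alpha = self.head_attention(k, adjacency, h)
            alpha = self._dropout(alpha, training, rng)
            outs.append((alpha @ (h @ self.weights[k]))
                        .leaky_relu(self.negative_slope))
        if mode == "concat":
            return concat(outs, axis=1)
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        return acc * (1.0 / self.n_heads)


def attention_coefficients(layer: GatLayer, head: int, adjacency: np.ndarray,
                           h: Tensor, i: int) -> np.ndarray:
    """Attention weights of node i over its neighbourhood Ne(i), in
    neighbour-index order.  Nonnegative, summing to 1."""
    neighbours = np.flatnonzero(adjacency[i])
    if neighbours.size == 0:
        raise RuntimeError(f"node {i} has an empty neighbourhood")
    alpha = layer.head_attention(head, adjacency, Tensor.as_tensor(h))
    return alpha.data[i, neighbours]


class GatStack:
    """A stack of GAT layers: concat heads on layers 1..L-1, average on L.

    Widths follow [f_in, d, ..., d] with per-head width d/n_heads under
    concatenation and d on the averaged final layer, so the embedding width
    is d throughout.
    """

    def __init__(self, f_in: int, d: int, n_layers: int, n_heads: int,
                 rng: np.random.Generator, negative_slope: float = 0.2,
                 dropout_rate: float = 0.2):
        if n_layers < 1:
            raise ValueError("need at least one layer")
        if d % n_heads != 0:
            raise ValueError(f"embed dim {d} not divisible by {n_heads} heads")
        self.layers: list[GatLayer] = []
        width = f_in
        for li in range(n_layers):
            final = li == n_layers - 1
            f_out = d if final else d // n_heads
            self.layers.append(
                GatLayer(width, f_out, n_heads, rng,
                         negative_slope=negative_slope,
                         dropout_rate=dropout_rate)
            )
            width = f_out if final else f_out * n_heads
        self.out_width = d

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, adjacency: np.ndarray, h: Tensor,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        for li, layer in enumerate(self.layers):
            mode = "average" if li == len(self.layers) - 1 else "concat"
            h = layer.forward(adjacency, h, mode=mode, training=training,
                              rng=rng)
        return h
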