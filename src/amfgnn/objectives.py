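"""Pair scoring and the composite training objective.

The score of a drug-disease pair is a probability: sigmoid of the head's
logit.  The head is a Kolmogorov-Arnold network on the concatenated fused
pair embedding [M_i ; D_j] (default), an MLP with the same interface (the
KAN ablation), or the literal inner product M_i . D_j (``dot``).

The objective combines binary cross-entropy over a pair set with two
cross-view contrastive regularisers:

    L = L_CE + w_MC * L_MC + w_DC * L_DC,

where each contrastive term uses the negative cosine distance
dis(u, v) = -u.v / (|u||v|) and averages, over all anchor/contrast pairs,
dis(m_i^1, m_i^2) - dis(m_i^1, m_j^2): aligned views of the same entity are
pulled together, views of different entities pushed apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat

__all__ = ["LossWeights", "score_pairs", "cross_entropy", "cosine_distance",
           "contrastive_loss", "total_loss"]

_CLAMP = 1e-12


@dataclass
class LossWeights:
    """Nonnegative weights of the two contrastive terms."""

    w_mc: float = 0.1
    w_dc: float = 0.1

    def __post_init__(self):
        if self.w_mc < 0 or self.w_dc < 0:
            raise ValueError("loss weights must be nonnegative")


def score_pairs(drug_emb: Tensor, disease_emb: Tensor,
                pairs: tuple[np.ndarray, np.ndarray], head=None,
                pair_features: str = "product") -> Tensor:
    """Probabilities for the given (drug_index, disease_index) pairs.

    head=None realises the literal dot-product scorer sigmoid(M_i . D_j).
    Otherwise ``head`` is any object with a forward(features) -> logits
    method; its input is the Hadamard product M_i * D_j (default), which
    generalises the inner-product score — a head summing identity
    activations of the products recovers it exactly — or the concatenation
    [M_i ; D_j] with pair_features='concat'.  Returns a vector of scores
    strictly inside (0, 1).
    """
    di, sj = pairs
    m = drug_emb[np.asarray(di)]
    d = disease_emb[np.asarray(sj)]
    if head is None:
        logits = (m * d).sum(axis=1)
    elif pair_features == "product":
        logits = head.forward(m * d).reshape(-1)
    elif pair_features == "concat":
        logits = head.forward(concat([m, d], axis=1)).reshape(-1)
    else:
        raise ValueError(f"unknown pair_features {pair_features!r}")
    return logits.sigmoid()


def cross_entropy(scores: Tensor, labels: np.ndarray,
                  reduction: str = "sum") -> Tensor:
    """Binary cross-entropy over a pair set.

    -sum_ij [S_ij ln S^_ij + (1-S_ij) ln(1-S^_ij)], with scores clamped at
    1e-12 before the logs.  reduction='mean' divides by the pair count.
    """
    labels = np.asarray(labels, dtype=float)
    scores = Tensor.as_tensor(scores)
    if scores.data.size == 0:
        raise ValueError("empty pair set")
    if scores.data.shape != labels.shape:
        raise ValueError("scores and labels must align")
    p = scores.clip(_CLAMP, 1.0 - _CLAMP)
    ll = Tensor(labels) * p.log() + Tensor(1.0 - labels) * (1.0 - p).log()
    loss = -ll.sum()
    if reduction == "mean":
        loss = loss * (1.0 / labels.size)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return loss


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Negative cosine similarity, in [-1, 1]; undefined for zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(-(u @ v) / (nu * nv))


def _row_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    n = ((x * x).sum(axis=1, keepdims=True) + eps).sqrt()
    return x / n


def contrastive_loss(view1: Tensor, view2: Tensor) -> Tensor:
    """Cross-view contrastive regulariser.

    (1/N^2) sum_i sum_j [dis(m_i^1, m_i^2) - dis(m_i^1, m_j^2)]
    = mean_ij cos(m_i^1, m_j^2) - mean_i cos(m_i^1, m_i^2),
    averaged over anchors as well as contrasts so the value is
    size-independent.  Minimised when paired rows align and unpaired rows
    anti-align.
    """
    view1 = Tensor.as_tensor(view1)
    view2 = Tensor.as_tensor(view2)
    if view1.shape != view2.shape:
        raise ValueError(f"view shapes differ: {view1.shape} vs {view2.shape}")
    if view1.shape[0] < 1:
        raise ValueError("need at least one row")
    u = _row_normalize(view1)
    v = _row_normalize(view2)
    cos = u @ v.T
    n = view1.shape[0]
    diag = cos[np.arange(n), np.arange(n)]
    return cos.sum() * (1.0 / (n * n)) - diag.sum() * (1.0 / n)


def total_loss(ce: Tensor, lmc: Tensor, ldc: Tensor,
               weights: LossWeights) -> Tensor:
    """L = L_CE + w_MC * L_MC + w_DC * L_DC."""
    return ce + weights.w_mc * Tensor.as_tensor(lmc) \
        + weights.w_dc * Tensor.as_tensor(ldc)
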