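"""Gate-augmented graph attention (GAT) layer.

One layer maps node embeddings X (rows x_i) and an adjacency A to new
embeddings in four steps:

1. transformed features      x'_i = W x_i
2. symmetric bilinear logits e_ij = x'_i^T E x'_j + x'_j^T E x'_i,
   defined only where A_ij > 0;
3. attention                 a_ij = softmax_{j in N_i}(e_ij) * A_ij,
   N_i = { j : A_ij > 0 } (always contains i, A has unit diagonal);
4. aggregation + gate        x''_i = sum_j a_ij x'_j,
                             c_i  = logistic(D . (x_i || x''_i) + b),
                             out_i = c_i x_i + (1 - c_i) x''_i.

The attention is deliberately bilinear and symmetric (no LeakyReLU,
no multi-head) and the gate is a per-node convex combination, so the
layer is a learned interpolation between a node's own embedding and
its attention-weighted neighborhood.

All operations run on :mod:`gatedock.autodiff` tensors and accept
either a single graph (N x F nodes, N x N adjacency) or a stack of
graphs with identical N (leading batch axis); gradients flow through
a weighted adjacency (the trainable cross-molecular graph) when one
is supplied as a tensor.

Note on weighted adjacencies: the softmax is normalized over N_i and
only then multiplied by A_ij, so rows of ``a`` sum to 1 exactly when
A is binary on its support; with Gaussian-weighted entries the row
sums are <= 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

LOGIT_CLIP = 50.0
MASK_SENTINEL = -1e9


@dataclass
class GatLayerParams:
    """Learnable parameters of one layer (shared across the A1/A2 passes)."""

    W: Tensor  # (F, F) feature transform
    E_att: Tensor  # (F, F) attention bilinear form
    D: Tensor  # (2F, 1) gate weights
    b: Tensor  # () gate bias

    @property
    def width(self) -> int:
        return self.W.shape[0]


def transform(X, params: GatLayerParams) -> Tensor:
    """x'_i = W x_i for every node (rowwise X W^T)."""
    return ad.matmul(ad.tensor(X), params.W.T)


def attention_logits(X, params: GatLayerParams, A) -> Tensor:
    """Symmetric bilinear attention logits on the support of A.

    Entries with A_ij == 0 carry a large negative sentinel so that a
    subsequent masked softmax assigns them exactly zero weight.
    """
    X = ad.tensor(X)
    A_data = A.data if isinstance(A, Tensor) else np.asarray(A)
    if X.shape[-2] != A_data.shape[-1]:
        raise ValueError(
            f"node count mismatch: X has {X.shape[-2]}, A has {A_data.shape[-1]}")
    xp = transform(X, params)
    s = ad.matmul(ad.matmul(xp, params.E_att), xp.T)
    e = ad.add(s, s.T)
    return ad.where_const(A_data > 0, e, MASK_SENTINEL)


def attention_weights(logits: Tensor, A) -> Tensor:
    """a_ij = softmax over N_i of e_ij, multiplied by A_ij.

    Max-subtracted for stability, logits clipped to +-LOGIT_CLIP
    before exponentiation, exact zeros off the support of A.
    """
    A_t = ad.tensor(A)
    support = A_t.data > 0
    masked = np.where(support, logits.data, -np.inf)
    row_max = masked.max(axis=-1, keepdims=True)  # finite: diagonal in support
    shifted = ad.clip(ad.sub(logits, row_max), -LOGIT_CLIP, LOGIT_CLIP)
    z = ad.where_const(support, ad.exp(shifted), 0.0)
    denom = ad.tsum(z, axis=-1, keepdims=True)
    return ad.mul(ad.div(z, denom), A_t)


def aggregate(X, a: Tensor, params: GatLayerParams) -> Tensor:
    """x''_i = sum_{j in N_i} a_ij x'_j."""
    return ad.matmul(a, transform(X, params))


def gated_update(X_in, X_agg, params: GatLayerParams) -> Tensor:
    """Convex gate between the input embedding and the aggregate.

    The gate weight vector D acts on the concatenation (x_i || x''_i);
    it is applied as two half-width products, which is the same dot
    product without materializing the concatenated matrix.
    """
    X_in, X_agg = ad.tensor(X_in), ad.tensor(X_agg)
    if X_in.shape != X_agg.shape:
        raise ValueError(f"shape mismatch: {X_in.shape} vs {X_agg.shape}")
    f = X_in.shape[-1]
    d_in, d_agg = ad.split2(params.D, f)
    z = ad.add(ad.add(ad.matmul(X_in, d_in), ad.matmul(X_agg, d_agg)), params.b)
    c = ad.sigmoid(z)  # (..., N, 1)
    # c*x + (1-c)*x'' written as x'' + c*(x - x'')
    return ad.add(X_agg, ad.mul(c, ad.sub(X_in, X_agg)))


def gat_layer(X, A, params: GatLayerParams) -> Tensor:
    """Full layer: logits -> attention -> aggregation -> gate."""
    X = ad.tensor(X)
    e = attention_logits(X, params, A)
    a = attention_weights(e, A)
    xagg = aggregate(X, a, params)
    return gated_update(X, xagg, params)
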