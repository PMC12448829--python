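"""Protein/function correlation attention with sparse top-k normalization.

Both sides share one mechanism: the hidden tensor (N_F x N_P x C) is
contracted over the non-attention node axis (by mean) to give one
feature vector per node; learned query/key projections and a bilinear
form produce an N x N score matrix passed through a sigmoid, scaled by
a scalar gain. Per row only the k largest scores are retained and
softmax-normalized; ties go to the lowest column index and the
retention mask is treated as constant in the backward pass
(straight-through), so gradients flow through retained entries only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, DataError


@dataclass
class AttentionParams:
    """Learnable parameters of one correlation head.

    u1, u3: C x d query/key projections; u2: d x d bilinear form;
    gain and bias are scalars (printed as matrix left-multiplier and
    additive offset with no stated shape).
    """

    u1: Tensor
    u2: Tensor
    u3: Tensor
    gain: Tensor
    bias: Tensor

    @classmethod
    def create(cls, channels: int, attn_dim: int, rng: np.random.Generator,
               prefix: str = "att") -> "AttentionParams":
        scale = 1.0 / np.sqrt(channels)
        p = cls(
            u1=Tensor(rng.normal(0, scale, (channels, attn_dim)), requires_grad=True),
            u2=Tensor(rng.normal(0, 1.0 / np.sqrt(attn_dim), (attn_dim, attn_dim)),
                      requires_grad=True),
            u3=Tensor(rng.normal(0, scale, (channels, attn_dim)), requires_grad=True),
            gain=Tensor(1.0, requires_grad=True),
            bias=Tensor(0.0, requires_grad=True),
        )
        p._prefix = prefix
        return p

    def named(self) -> dict:
        prefix = getattr(self, "_prefix", "att")
        return {f"{prefix}.u1": self.u1, f"{prefix}.u2": self.u2,
                f"{prefix}.u3": self.u3, f"{prefix}.gain": self.gain,
                f"{prefix}.bias": self.bias}


@dataclass
class SparseAttentionMatrix:
    """Row-normalized sparse attention weights (each row: <= k nonzeros)."""

    matrix: Tensor
    k: int

    @property
    def data(self) -> np.ndarray:
        return self.matrix.data


def _correlation(node_features: Tensor, params: AttentionParams) -> Tensor:
    query = ad.matmul(node_features, params.u1)
    key = ad.matmul(node_features, params.u3)
    scores = ad.matmul(ad.matmul(query, params.u2), key.T)
    return params.gain * ad.sigmoid(scores + params.bias)


def function_correlation(state, params: AttentionParams) -> Tensor:
    """N_F x N_F correlation scores from the hidden tensor.

    The protein axis is contracted by mean before the bilinear form.
    """
    state = ad.as_tensor(state)
    if state.ndim != 3:
        raise DataError(f"hidden state must be 3-axis, got shape {state.shape}")
    if params.u1.shape[0] != state.shape[2]:
        raise DataError(
            f"channel mismatch: state has {state.shape[2]}, params expect {params.u1.shape[0]}")
    return _correlation(state.mean(axis=1), params)


def protein_correlation(state, params: AttentionParams) -> Tensor:
    """N_P x N_P correlation scores (function axis contracted by mean)."""
    state = ad.as_tensor(state)
    if state.ndim != 3:
        raise DataError(f"hidden state must be 3-axis, got shape {state.shape}")
    if params.u1.shape[0] != state.shape[2]:
        raise DataError(
            f"channel mismatch: state has {state.shape[2]}, params expect {params.u1.shape[0]}")
    return _correlation(state.mean(axis=0), params)


def resolve_k(n_nodes: int, ratio: float = 0.25) -> int:
    """Per-row retention count: max(1, floor(n_nodes * ratio))."""
    if n_nodes < 1:
        raise ConfigError("n_nodes must be >= 1")
    if not 0 < ratio <= 1:
        raise ConfigError("ratio must be in (0, 1]")
    return max(1, int(np.floor(n_nodes * ratio)))


def topk_mask(scores: np.ndarray, k: int) -> np.ndarray:
    """Binary mask of the k largest entries per row; ties -> lowest column."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    k = min(k, scores.shape[1])
    # stable sort on negated scores: equal values keep original column order
    order = np.argsort(-scores, axis=1, kind="stable")
    mask = np.zeros_like(scores)
    np.put_along_axis(mask, order[:, :k], 1.0, axis=1)
    return mask


def sparse_topk_normalize(scores, k: int) -> SparseAttentionMatrix:
    """Retain the top-k scores per row and softmax over the retained set.

    Accepts a plain array or a Tensor; with a Tensor the mask is a
    constant and gradients flow only through retained entries.
    """
    t = ad.as_tensor(scores)
    mask = topk_mask(t.data, k)
    # subtracting the (constant) row max leaves the softmax value and its
    # gradient unchanged but avoids overflow
    shift = np.where(mask > 0, t.data, -np.inf).max(axis=1, keepdims=True)
    z = ad.texp(t - Tensor(shift)) * Tensor(mask)
    normalized = z / z.sum(axis=1, keepdims=True)
    return SparseAttentionMatrix(matrix=normalized, k=min(k, t.shape[1]))


def attention_edge_list(att: SparseAttentionMatrix, ids) -> list:
    """(source_id, target_id, weight) rows for nonzero attention entries."""
    ids = list(ids)
    rows, cols = np.nonzero(att.data)
    return [(ids[r], ids[c], float(att.data[r, c])) for r, c in zip(rows, cols)]
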