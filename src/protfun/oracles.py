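"""Independent brute-force reference implementations, used only by tests.

Each function recomputes a quantity from its definition with explicit
loops and set arithmetic, sharing no code with the production paths.
Clarity over speed: O(n^4) is fine at test scale (<= 10 nodes,
sequences <= 50).
"""

from __future__ import annotations

import math

import numpy as np


def naive_dcc(x: np.ndarray, kernel: np.ndarray, dilation: int,
              bias: np.ndarray | None = None) -> np.ndarray:
    """Double-loop dilated causal convolution.

    out[t, c_out] = sum_s sum_cin kernel[s, cin, c_out] * x[t - dilation*s, cin]
    with out-of-range inputs read as zero. A 1-D kernel is interpreted as
    scalar taps applied channel-wise.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim == 1:
        kernel = np.stack([v * np.eye(x.shape[1]) for v in kernel])
    length, _ = x.shape
    c_out = kernel.shape[2]
    out = np.zeros((length, c_out))
    for t in range(length):
        for s in range(kernel.shape[0]):
            src = t - dilation * s
            if src < 0:
                continue
            for co in range(c_out):
                for ci in range(x.shape[1]):
                    out[t, co] += kernel[s, ci, co] * x[src, ci]
    if bias is not None:
        out = out + np.asarray(bias, dtype=float)
    return out


def naive_attention(state: np.ndarray, u1: np.ndarray, u2: np.ndarray,
                    u3: np.ndarray, gain: float, bias: float,
                    axis: str = "function") -> np.ndarray:
    """Index-wise correlation matrix on the chosen node axis.

    Node features are the mean over the other node axis; entry (a, b) is
    gain * logistic( (feat_a @ u1) @ u2 @ (feat_b @ u3) + bias ).
    """
    state = np.asarray(state, dtype=float)
    n = state.shape[0] if axis == "function" else state.shape[1]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            feat_a = (state[a].mean(axis=0) if axis == "function"
                      else state[:, a].mean(axis=0))
            feat_b = (state[b].mean(axis=0) if axis == "function"
                      else state[:, b].mean(axis=0))
            score = float(feat_a @ u1 @ u2 @ (feat_b @ u3)) + bias
            out[a, b] = gain * (1.0 / (1.0 + math.exp(-score)))
    return out


def naive_topk_rows(scores: np.ndarray, k: int) -> np.ndarray:
    """Per-row top-k softmax by explicit sorting (ties: lowest index)."""
    scores = np.asarray(scores, dtype=float)
    out = np.zeros_like(scores)
    for r in range(scores.shape[0]):
        ranked = sorted(range(scores.shape[1]),
                        key=lambda c: (-scores[r, c], c))[:min(k, scores.shape[1])]
        exps = {c: math.exp(scores[r, c] - max(scores[r, c] for c in ranked))
                for c in ranked}
        total = sum(exps.values())
        for c in ranked:
            out[r, c] = exps[c] / total
    return out


def naive_diffusion(x: np.ndarray, mats: list, weights: list,
                    n_steps: int, axis: str) -> np.ndarray:
    """Explicit power-sum diffusion: sum over terms and steps of
    M_term^n . x . W_term[n], mixing along the stated node axis."""
    x = np.asarray(x, dtype=float)
    out = np.zeros((x.shape[0], x.shape[1], weights[0][0].shape[1]))
    for mat, w_per_step in zip(mats, weights):
        mat = np.asarray(mat, dtype=float)
        power = np.eye(mat.shape[0])
        for n in range(n_steps):
            power = power @ mat
            mixed = np.zeros_like(x)
            if axis == "function":
                for i in range(x.shape[0]):
                    for i2 in range(x.shape[0]):
                        mixed[i] += power[i, i2] * x[i2]
            else:
                for p in range(x.shape[1]):
                    for p2 in range(x.shape[1]):
                        mixed[:, p] += power[p, p2] * x[:, p2]
            out = out + mixed @ np.asarray(w_per_step[n], dtype=float)
    return out


def sweep_fmax(scores: np.ndarray, truth: np.ndarray,
               grid=None) -> tuple:
    """Exhaustive threshold sweep from raw set arithmetic."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if grid is None:
        grid = [round(0.01 * i, 2) for i in range(1, 101)]
    best_f, best_h = 0.0, grid[0]
    for h in grid:
        precisions, recalls = [], []
        for j in range(scores.shape[0]):
            predicted = {i for i in range(scores.shape[1]) if scores[j, i] >= h}
            true_set = {i for i in range(truth.shape[1]) if truth[j, i] == 1}
            hit = predicted & true_set
            precisions.append(len(hit) / len(predicted) if predicted else 0.0)
            recalls.append(len(hit) / len(true_set))
        p_bar = sum(precisions) / len(precisions)
        r_bar = sum(recalls) / len(recalls)
        f = 0.0 if p_bar + r_bar == 0 else 2 * p_bar * r_bar / (p_bar + r_bar)
        if f > best_f:
            best_f, best_h = f, h
    return best_f, best_h


def mannwhitney_auc(scores, labels) -> float | None:
    """Pair-counting AUC: P(random positive outranks random negative),
    ties counting half."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def receptive_field_by_impulse(stack_fn, length: int = 128) -> int:
    """Empirical receptive field: feed unit impulses at each position and
    count how many input positions influence the last output row."""
    influencing = 0
    base = np.zeros((length, 1))
    ref = stack_fn(base)
    for t in range(length):
        probe = base.copy()
        probe[t, 0] = 1.0
        if not np.allclose(stack_fn(probe)[-1], ref[-1]):
            influencing += 1
    return influencing
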