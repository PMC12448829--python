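"""Adaptive diffusion graph convolution blocks.

Function block (unidirectional): Z = sum_n A^n X W_{n,1} + Ftil^n X W_{n,2},
mixing along the function axis only. Protein block (bidirectional):
Z = sum_n Rf^n X U_{n,1} + Rb^n X U_{n,2} + Ptil^n X U_{n,3}, mixing
along the protein axis. The prior matrices (A, Rf, Rb) enter as
constants and are never modified; the attention matrices are Tensors
through which gradients flow (including through their matrix powers).

The prior function adjacency is row-normalized by default so its powers
stay bounded; raw powers are available for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, DataError
from .protein_graph import row_normalize


@dataclass
class DiffusionConvParams:
    """Per-step channel-mixing weights for one block.

    `weights` maps role name -> list of N Tensors (C_in x C_out):
    function block roles "prior"/"adaptive"; protein block roles
    "forward"/"backward"/"adaptive".
    """

    steps: int
    weights: dict

    def __post_init__(self):
        if self.steps < 1:
            raise ConfigError("diffusion steps must be >= 1")
        for role, ws in self.weights.items():
            if len(ws) != self.steps:
                raise ConfigError(f"role {role!r}: need one weight per step")

    @classmethod
    def create(cls, roles, steps: int, c_in: int, c_out: int,
               rng: np.random.Generator, prefix: str = "gc") -> "DiffusionConvParams":
        scale = 1.0 / np.sqrt(c_in * steps * len(roles))
        weights = {
            role: [Tensor(rng.normal(0, scale, (c_in, c_out)), requires_grad=True)
                   for _ in range(steps)]
            for role in roles
        }
        p = cls(steps=steps, weights=weights)
        p._prefix = prefix
        return p

    def named(self) -> dict:
        prefix = getattr(self, "_prefix", "gc")
        return {f"{prefix}.{role}.step{n}": w
                for role, ws in self.weights.items() for n, w in enumerate(ws)}


def _check_state(x, n_nodes: int, axis: int) -> Tensor:
    x = ad.as_tensor(x)
    if x.ndim != 3:
        raise DataError(f"hidden state must be 3-axis, got shape {x.shape}")
    if x.shape[axis] != n_nodes:
        raise DataError(
            f"state axis {axis} has size {x.shape[axis]}, graph has {n_nodes} nodes")
    return x


def normalize_prior(a_f: np.ndarray, mode: str = "row") -> np.ndarray:
    """Prepare the prior function adjacency for diffusion ("row" or "raw")."""
    if mode == "row":
        return row_normalize(a_f)
    if mode == "raw":
        return np.asarray(a_f, dtype=float)
    raise ConfigError(f"unknown prior normalization mode {mode!r}")


def function_graph_conv(x, a_f: np.ndarray, f_att,
                        params: DiffusionConvParams) -> Tensor:
    """N-step unidirectional diffusion over the function axis."""
    a_f = np.asarray(a_f, dtype=float)
    x = _check_state(x, a_f.shape[0], axis=0)
    f_mat = f_att.matrix if hasattr(f_att, "matrix") else ad.as_tensor(f_att)
    prior_pows = [a_f]
    for _ in range(params.steps - 1):
        prior_pows.append(prior_pows[-1] @ a_f)
    att_pows = ad.matrix_powers(f_mat, params.steps)
    out = None
    for n in range(params.steps):
        term = ad.last_linear(ad.mix_function_axis(Tensor(prior_pows[n]), x),
                              params.weights["prior"][n])
        term = term + ad.last_linear(ad.mix_function_axis(att_pows[n], x),
                                     params.weights["adaptive"][n])
        out = term if out is None else out + term
    return out


def function_graph_conv_adaptive_only(x, f_att,
                                      params: DiffusionConvParams) -> Tensor:
    """Prior-free variant: Z = sum_n Ftil^n X W_{n,2}."""
    f_mat = f_att.matrix if hasattr(f_att, "matrix") else ad.as_tensor(f_att)
    x = _check_state(x, f_mat.shape[0], axis=0)
    att_pows = ad.matrix_powers(f_mat, params.steps)
    out = None
    for n in range(params.steps):
        term = ad.last_linear(ad.mix_function_axis(att_pows[n], x),
                              params.weights["adaptive"][n])
        out = term if out is None else out + term
    return out


def protein_graph_conv(x, diff, p_att, params: DiffusionConvParams) -> Tensor:
    """N-step bidirectional diffusion over the protein axis."""
    r_f = np.asarray(diff.forward, dtype=float)
    r_b = np.asarray(diff.backward, dtype=float)
    x = _check_state(x, r_f.shape[0], axis=1)
    p_mat = p_att.matrix if hasattr(p_att, "matrix") else ad.as_tensor(p_att)
    fwd_pows, bwd_pows = [r_f], [r_b]
    for _ in range(params.steps - 1):
        fwd_pows.append(fwd_pows[-1] @ r_f)
        bwd_pows.append(bwd_pows[-1] @ r_b)
    att_pows = ad.matrix_powers(p_mat, params.steps)
    out = None
    for n in range(params.steps):
        term = ad.last_linear(ad.mix_protein_axis(Tensor(fwd_pows[n]), x),
                              params.weights["forward"][n])
        term = term + ad.last_linear(ad.mix_protein_axis(Tensor(bwd_pows[n]), x),
                                     params.weights["backward"][n])
        term = term + ad.last_linear(ad.mix_protein_axis(att_pows[n], x),
                                     params.weights["adaptive"][n])
        out = term if out is None else out + term
    return out


def protein_graph_conv_adaptive_only(x, p_att,
                                     params: DiffusionConvParams) -> Tensor:
    """Prior-free variant: Z = sum_n Ptil^n X U_{n,3}."""
    p_mat = p_att.matrix if hasattr(p_att, "matrix") else ad.as_tensor(p_att)
    x = _check_state(x, p_mat.shape[0], axis=1)
    att_pows = ad.matrix_powers(p_mat, params.steps)
    out = None
    for n in range(params.steps):
        term = ad.last_linear(ad.mix_protein_axis(att_pows[n], x),
                              params.weights["adaptive"][n])
        out = term if out is None else out + term
    return out
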