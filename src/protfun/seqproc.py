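"""Sequence Processing Block: embedder seam, truncation, stacked dilated
causal convolutions, gated multi-scale aggregation and global/local fusion.

The pretrained protein language model is an adapter: any callable
mapping a sequence to an L x K per-residue matrix satisfies the
contract (the deterministic stub in :mod:`protfun.fixtures` is the test
double; a real transformer adapter can be plugged in unchanged). The
embedder output is treated as frozen — it enters the autodiff graph as
a constant.

Dilated causal convolution uses left zero-padding so output length
equals input length and output position t depends only on inputs <= t.
With kernel width 3 and dilations 1, 2, 4, 8 the receptive fields of
the four stacked layers span 3, 7, 15 and 31 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, DataError, EmbeddingError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_ALPHABET = AA_ALPHABET + "X"

#: Sequences longer than this are truncated ...
MAX_SEQ_LEN = 1024
#: ... to this many leading residues.
TRUNCATE_TO = 1000

DEFAULT_EMBED_DIM = 1280
DEFAULT_KERNEL_WIDTH = 3
DEFAULT_DILATIONS = (1, 2, 4, 8)


def preprocess_sequence(seq: str) -> str:
    """Validate a residue string and apply the length-cap truncation.

    Sequences exceeding ``MAX_SEQ_LEN`` residues are cut to the first
    ``TRUNCATE_TO``; anything at or under the cap passes unchanged.
    """
    if not seq:
        raise DataError("empty amino-acid sequence")
    bad = set(seq) - set(EXTENDED_ALPHABET)
    if bad:
        raise DataError(f"sequence contains non-amino-acid characters: {sorted(bad)}")
    if len(seq) > MAX_SEQ_LEN:
        return seq[:TRUNCATE_TO]
    return seq


def embed(seq: str, embedder, seq_id: str | None = None) -> np.ndarray:
    """Run the (frozen) embedder adapter on a preprocessed sequence."""
    if not seq:
        raise DataError("empty amino-acid sequence")
    try:
        matrix = np.asarray(embedder(seq), dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise EmbeddingError(f"embedder failed for sequence {seq_id or seq[:12]!r}: {exc}") from exc
    if matrix.ndim != 2 or matrix.shape[0] != len(seq):
        raise EmbeddingError(
            f"embedder returned shape {matrix.shape} for length-{len(seq)} sequence "
            f"{seq_id or ''}")
    if not np.isfinite(matrix).all():
        raise EmbeddingError(f"non-finite embedding values for sequence {seq_id or ''}")
    return matrix


def receptive_field(q: int, kernel_width: int, dilations) -> int:
    """Input span influencing one output of the first `q` stacked layers.

    Closed form ``1 + (kernel_width - 1) * sum(dilations[:q])``; the
    impulse-response tests verify it empirically.
    """
    if q < 1:
        raise ConfigError("q must be >= 1")
    if len(dilations) < q:
        raise ConfigError("need a dilation per layer")
    return 1 + (kernel_width - 1) * int(sum(dilations[:q]))


@dataclass
class DccLayer:
    """One dilated causal convolution layer.

    `taps` is a list of S weight Tensors, each C_in x C_out; tap s reads
    the input `dilation * s` positions back. `bias` is per output channel.
    """

    taps: list
    bias: Tensor
    dilation: int

    def __post_init__(self):
        if self.dilation < 1:
            raise ConfigError("dilation must be >= 1")
        if not self.taps:
            raise ConfigError("kernel must have at least one tap")

    @classmethod
    def from_kernel(cls, kernel, dilation: int, channels: int) -> "DccLayer":
        """Scalar kernel taps applied identically to every channel."""
        taps = [Tensor(float(v) * np.eye(channels)) for v in kernel]
        return cls(taps=taps, bias=Tensor(np.zeros(channels)), dilation=dilation)

    @classmethod
    def random(cls, width: int, c_in: int, c_out: int, dilation: int,
               rng: np.random.Generator) -> "DccLayer":
        scale = 1.0 / np.sqrt(width * c_in)
        taps = [Tensor(rng.normal(0, scale, (c_in, c_out)), requires_grad=True)
                for _ in range(width)]
        return cls(taps=taps, bias=Tensor(np.zeros(c_out), requires_grad=True),
                   dilation=dilation)

    @property
    def width(self) -> int:
        return len(self.taps)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.as_tensor(x)
        out = None
        for s, tap in enumerate(self.taps):
            term = ad.last_linear(ad.shift_rows(x, self.dilation * s), tap)
            out = term if out is None else out + term
        return out + self.bias


def dcc_layer(x, kernel, dilation: int, bias=None) -> np.ndarray:
    """Functional form of one DCC layer on a plain array.

    `kernel` is either a 1-D scalar tap vector (channel-preserving) or
    an S x C_in x C_out weight array.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim == 1:
        taps = [float(v) * np.eye(x.shape[1]) for v in kernel]
    else:
        taps = list(kernel)
    layer = DccLayer(taps=[Tensor(t) for t in taps],
                     bias=Tensor(np.zeros(taps[0].shape[1]) if bias is None else bias),
                     dilation=dilation)
    return layer(Tensor(x)).data


def gated_multiscale_fusion(features, gate_weights, gate_biases) -> Tensor:
    """Gate-weighted sum of the Q per-layer DCC feature maps.

    Per layer q: alpha_q = sigmoid(concat(features) @ W_q + b_q), an
    (L x C) gate in (0, 1); the output is sum_q alpha_q * features[q].
    """
    features = [ad.as_tensor(f) for f in features]
    shapes = {f.shape for f in features}
    if len(shapes) != 1:
        raise DataError(f"multi-scale features disagree in shape: {shapes}")
    if len(gate_weights) != len(features) or len(gate_biases) != len(features):
        raise ConfigError("need one gate per feature map")
    stacked = ad.concatenate(features, axis=1)  # L x (Q*C)
    out = None
    for f, w, b in zip(features, gate_weights, gate_biases):
        alpha = ad.sigmoid(ad.last_linear(stacked, w) + b)
        term = alpha * f
        out = term if out is None else out + term
    return out


def fuse_global_local(f_global, f_dcc, w_g, b_g) -> Tensor:
    """Gated fusion of the global embedding and the local DCC features.

    gate = sigmoid([f_global; f_dcc] @ W_g + b_g);  out = gate * (f_global + f_dcc).
    W_g maps 2K -> K.
    """
    f_global, f_dcc = ad.as_tensor(f_global), ad.as_tensor(f_dcc)
    if f_global.shape != f_dcc.shape:
        raise DataError(
            f"global/local feature shapes differ: {f_global.shape} vs {f_dcc.shape}")
    gate = ad.sigmoid(ad.last_linear(ad.concatenate([f_global, f_dcc], axis=1), w_g) + b_g)
    return gate * (f_global + f_dcc)


def pool_to_protein(x_h, mode: str = "mean") -> Tensor:
    """Reduce an L x K residue matrix to one length-K protein vector."""
    x_h = ad.as_tensor(x_h)
    if x_h.shape[0] < 1:
        raise DataError("cannot pool an empty feature matrix")
    if mode == "mean":
        return x_h.mean(axis=0)
    if mode == "max":
        # max-pool: constant argmax mask, gradient to the max rows only
        idx = np.argmax(x_h.data, axis=0)
        mask = np.zeros_like(x_h.data)
        mask[idx, np.arange(x_h.data.shape[1])] = 1.0
        return (x_h * Tensor(mask)).sum(axis=0)
    raise ConfigError(f"unknown pooling mode {mode!r}")


@dataclass
class SequenceBlock:
    """The full sequence-processing block with trainable parameters.

    Pipeline per protein: frozen embedding (L x K) -> linear projection
    to `channels` -> Q stacked DCC layers -> gated multi-scale
    aggregation -> global/local gated fusion -> pooling.
    """

    projection: Tensor        # K x C
    layers: list              # Q DccLayer, each C -> C
    gate_weights: list        # Q tensors, (Q*C) x C
    gate_biases: list         # Q tensors, C
    fusion_weight: Tensor     # 2C x C
    fusion_bias: Tensor       # C
    pooling: str = "mean"
    params: dict = field(default_factory=dict, repr=False)

    @classmethod
    def create(cls, embed_dim: int, channels: int, kernel_width: int,
               dilations, rng: np.random.Generator,
               pooling: str = "mean") -> "SequenceBlock":
        q = len(dilations)
        proj = Tensor(rng.normal(0, 1.0 / np.sqrt(embed_dim), (embed_dim, channels)),
                      requires_grad=True)
        layers = [DccLayer.random(kernel_width, channels, channels, d, rng)
                  for d in dilations]
        gate_w = [Tensor(rng.normal(0, 1.0 / np.sqrt(q * channels), (q * channels, channels)),
                         requires_grad=True) for _ in range(q)]
        gate_b = [Tensor(np.zeros(channels), requires_grad=True) for _ in range(q)]
        fuse_w = Tensor(rng.normal(0, 1.0 / np.sqrt(2 * channels), (2 * channels, channels)),
                        requires_grad=True)
        fuse_b = Tensor(np.zeros(channels), requires_grad=True)
        block = cls(projection=proj, layers=layers, gate_weights=gate_w,
                    gate_biases=gate_b, fusion_weight=fuse_w, fusion_bias=fuse_b,
                    pooling=pooling)
        block.params = block._collect_params()
        return block

    def _collect_params(self) -> dict:
        params = {"spb.projection": self.projection,
                  "spb.fusion_w": self.fusion_weight,
                  "spb.fusion_b": self.fusion_bias}
        for i, layer in enumerate(self.layers):
            for s, tap in enumerate(layer.taps):
                params[f"spb.dcc{i}.tap{s}"] = tap
            params[f"spb.dcc{i}.bias"] = layer.bias
        for i, (w, b) in enumerate(zip(self.gate_weights, self.gate_biases)):
            params[f"spb.gate{i}.w"] = w
            params[f"spb.gate{i}.b"] = b
        return params

    def __call__(self, f_global: np.ndarray) -> tuple:
        """Return (residue-level X_h, pooled protein vector) as Tensors."""
        projected = ad.last_linear(Tensor(f_global), self.projection)
        feats = []
        current = projected
        for layer in self.layers:
            current = layer(current)
            feats.append(current)
        f_dcc = gated_multiscale_fusion(feats, self.gate_weights, self.gate_biases)
        x_h = fuse_global_local(projected, f_dcc, self.fusion_weight, self.fusion_bias)
        return x_h, pool_to_protein(x_h, self.pooling)
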