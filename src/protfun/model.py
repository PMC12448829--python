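"""Model assembly, loss, training loop and prediction.

The network composes the sequence block with stacked
(attention + protein-graph conv + function-graph conv) layers over a
hidden tensor indexed (function, protein, channel). The initial hidden
tensor broadcasts pooled per-protein sequence features along the
function axis and adds a learned per-function embedding. A shared
linear head maps the final channels to one logit per (protein, term).

The prior graph matrices are constants of the computation graph; their
checksums are recorded before and after training and must not change.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .attention import (AttentionParams, function_correlation,
                        protein_correlation, resolve_k, sparse_topk_normalize)
from .autodiff import Adam, Tensor
from .errors import ConfigError, DataError
from .graphconv import (DiffusionConvParams, function_graph_conv,
                        function_graph_conv_adaptive_only, normalize_prior,
                        protein_graph_conv, protein_graph_conv_adaptive_only)
from .protein_graph import DiffusionPair
from .seqproc import SequenceBlock


@dataclass
class ModelConfig:
    embed_dim: int = 1280
    channels: int = 32
    attn_dim: int = 8
    n_steps: int = 2
    n_layers: int = 2
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 50
    seed: int = 42
    topk_ratio: float = 0.25
    learnable_lambda: bool = False
    evalue_threshold: float = 1e-10
    kernel_width: int = 3
    dilations: tuple = (1, 2, 4, 8)
    block_order: tuple = ("protein", "function")
    pooling: str = "mean"
    prior_norm: str = "row"
    use_priors: bool = True
    train_fraction: float = 0.8

    def __post_init__(self):
        if min(self.embed_dim, self.channels, self.attn_dim, self.n_steps,
               self.n_layers, self.batch_size, self.epochs) < 1:
            raise ConfigError("all size parameters must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")
        if not 0 < self.topk_ratio <= 1:
            raise ConfigError("topk_ratio must be in (0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if set(self.block_order) - {"protein", "function"}:
            raise ConfigError("block_order entries must be 'protein' or 'function'")
        self.dilations = tuple(int(d) for d in self.dilations)
        self.block_order = tuple(self.block_order)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class Model:
    """Assembled network over fixed graphs and frozen embeddings."""

    def __init__(self, config: ModelConfig, a_f: np.ndarray,
                 diffusion: DiffusionPair, embeddings: dict, protein_ids,
                 terms):
        self.config = config
        self.protein_ids = list(protein_ids)
        self.terms = list(terms)
        n_f, n_p = len(self.terms), len(self.protein_ids)
        if a_f.shape != (n_f, n_f):
            raise ConfigError(f"function adjacency {a_f.shape} vs {n_f} terms")
        if diffusion.forward.shape != (n_p, n_p):
            raise ConfigError(f"diffusion matrices {diffusion.forward.shape} vs {n_p} proteins")
        missing = [p for p in self.protein_ids if p not in embeddings]
        if missing:
            raise DataError(f"missing embeddings for proteins: {missing[:5]}")
        for pid in self.protein_ids:
            if embeddings[pid].shape[1] != config.embed_dim:
                raise ConfigError(
                    f"embedding width {embeddings[pid].shape[1]} for {pid} "
                    f"!= configured {config.embed_dim}")

        self.a_f_raw = np.asarray(a_f, dtype=float)
        self.a_f = normalize_prior(self.a_f_raw, config.prior_norm)
        self.r_f = np.asarray(diffusion.forward, dtype=float)
        self.r_b = np.asarray(diffusion.backward, dtype=float)
        self.diffusion = DiffusionPair(forward=self.r_f, backward=self.r_b)
        self.embeddings = {pid: np.asarray(embeddings[pid], dtype=float)
                           for pid in self.protein_ids}

        rng = np.random.default_rng(config.seed)
        c = config.channels
        self.seq_block = SequenceBlock.create(
            config.embed_dim, c, config.kernel_width, config.dilations, rng,
            pooling=config.pooling)
        self.function_embedding = Tensor(rng.normal(0, 0.1, (n_f, c)),
                                         requires_grad=True)
        self.attn_f, self.attn_p = [], []
        self.conv_f, self.conv_p = [], []
        for layer in range(config.n_layers):
            self.attn_f.append(AttentionParams.create(c, config.attn_dim, rng,
                                                      prefix=f"l{layer}.attf"))
            self.attn_p.append(AttentionParams.create(c, config.attn_dim, rng,
                                                      prefix=f"l{layer}.attp"))
            self.conv_f.append(DiffusionConvParams.create(
                ("prior", "adaptive"), config.n_steps, c, c, rng,
                prefix=f"l{layer}.convf"))
            self.conv_p.append(DiffusionConvParams.create(
                ("forward", "backward", "adaptive"), config.n_steps, c, c, rng,
                prefix=f"l{layer}.convp"))
        self.head_w = Tensor(rng.normal(0, 1.0 / np.sqrt(c), (c, 1)),
                             requires_grad=True)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)
        # bounded sparsity ratio, squashed to (0, 1] when learnable
        self.lambda_f = Tensor(0.0, requires_grad=config.learnable_lambda)
        self.lambda_p = Tensor(0.0, requires_grad=config.learnable_lambda)

        self.params = dict(self.seq_block.params)
        self.params["function_embedding"] = self.function_embedding
        for p in (*self.attn_f, *self.attn_p, *self.conv_f, *self.conv_p):
            self.params.update(p.named())
        self.params["head.w"] = self.head_w
        self.params["head.b"] = self.head_b
        if config.learnable_lambda:
            self.params["lambda_f"] = self.lambda_f
            self.params["lambda_p"] = self.lambda_p

    # -- plumbing ------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def prior_checksums(self) -> dict:
        return {"a_f": _checksum(self.a_f), "a_f_raw": _checksum(self.a_f_raw),
                "r_f": _checksum(self.r_f), "r_b": _checksum(self.r_b)}

    def _ratio(self, raw: Tensor) -> float:
        if self.config.learnable_lambda:
            return float(1.0 / (1.0 + np.exp(-raw.data)))  # sigmoid, in (0, 1)
        return self.config.topk_ratio

    # -- forward -------------------------------------------------------
    def forward(self, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Full-graph forward pass returning N_P x N_F logits."""
        cfg = self.config
        if train and rng is None:
            rng = np.random.default_rng(cfg.seed)
        pooled = ad.stack(
            [self.seq_block(self.embeddings[pid])[1] for pid in self.protein_ids],
            axis=0)  # N_P x C
        x = ad.reshape(pooled, (1, self.n_proteins, cfg.channels)) + \
            ad.reshape(self.function_embedding, (self.n_terms, 1, cfg.channels))
        k_f = resolve_k(self.n_terms, self._ratio(self.lambda_f))
        k_p = resolve_k(self.n_proteins, self._ratio(self.lambda_p))
        for layer in range(cfg.n_layers):
            f_att = sparse_topk_normalize(
                function_correlation(x, self.attn_f[layer]), k_f)
            p_att = sparse_topk_normalize(
                protein_correlation(x, self.attn_p[layer]), k_p)
            for block in cfg.block_order:
                if block == "protein":
                    if cfg.use_priors:
                        z = protein_graph_conv(x, self.diffusion, p_att,
                                               self.conv_p[layer])
                    else:
                        z = protein_graph_conv_adaptive_only(x, p_att,
                                                             self.conv_p[layer])
                else:
                    if cfg.use_priors:
                        z = function_graph_conv(x, self.a_f, f_att,
                                                self.conv_f[layer])
                    else:
                        z = function_graph_conv_adaptive_only(x, f_att,
                                                              self.conv_f[layer])
                # residual skip: the diffusion sums start at step 1, so
                # without it repeated row-stochastic mixing erases
                # per-node identity and the net cannot fit
                x = x + ad.dropout(ad.relu(z), cfg.dropout, rng, train)
        logits = ad.last_linear(x, self.head_w) + self.head_b  # N_F x N_P x 1
        return ad.reshape(logits, (self.n_terms, self.n_proteins)).T

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=float)


def assemble_model(config: ModelConfig, function_adjacency, diffusion,
                   embeddings: dict, protein_ids=None, terms=None) -> Model:
    """Build a :class:`Model`; accepts the graph dataclasses or raw arrays."""
    a_f = getattr(function_adjacency, "matrix", function_adjacency)
    if terms is None:
        terms = getattr(function_adjacency, "terms", None)
        if terms is None:
            raise ConfigError("terms must be provided when passing a raw adjacency")
    if protein_ids is None:
        protein_ids = list(embeddings)
    return Model(config, np.asarray(a_f, dtype=float), diffusion, embeddings,
                 protein_ids, terms)


def bce_with_logits_loss(logits, labels, printed_variant: bool = False):
    """Mean binary cross-entropy on logits.

    Standard numerically stable form:
    mean( max(x, 0) - x*y + log(1 + exp(-|x|)) ). The `printed_variant`
    flag swaps in log(1 + exp(1 - |x|)) for comparison experiments.
    Works on Tensors (differentiable) and plain arrays alike.
    """
    y = labels.data if isinstance(labels, Tensor) else np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("labels must be binary")
    x = ad.as_tensor(logits)
    if x.shape != y.shape:
        raise DataError(f"logits {x.shape} and labels {y.shape} differ in shape")
    yt = Tensor(y)
    inner = ad.softplus(1.0 - x.abs()) if printed_variant else ad.softplus(-x.abs())
    loss = (x.relu() - x * yt + inner).mean()
    return loss if isinstance(logits, Tensor) else float(loss.data)


def split_proteins(labels: np.ndarray, fraction: float = 0.8,
                   seed: int = 42) -> tuple:
    """Random train/test split by protein, patched so that every term
    with any positive keeps at least one training positive."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = max(1, int(round(fraction * n)))
    train = list(order[:n_train])
    test = list(order[n_train:])
    for term in range(labels.shape[1]):
        if labels[:, term].sum() == 0:
            continue
        if labels[train, term].sum() == 0:
            carrier = next(j for j in test if labels[j, term] > 0)
            test.remove(carrier)
            train.append(carrier)
    return np.array(sorted(train)), np.array(sorted(test))


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    best_epoch: int = -1
    best_loss: float = float("inf")
    checksums_before: dict = field(default_factory=dict)
    checksums_after: dict = field(default_factory=dict)


def train(model: Model, labels: np.ndarray, config: ModelConfig | None = None,
          train_idx=None) -> TrainHistory:
    """Train with Adam on BCE-with-logits; returns the loss history.

    The batch size counts proteins whose loss rows enter one optimizer
    step; the forward pass always spans the full graph. The best-loss
    parameter snapshot is restored at the end.
    """
    config = config or model.config
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (model.n_proteins, model.n_terms):
        raise DataError(f"labels {labels.shape} vs model "
                        f"({model.n_proteins}, {model.n_terms})")
    if train_idx is None:
        train_idx = np.arange(model.n_proteins)
    train_idx = np.asarray(train_idx, dtype=int)

    optimizer = Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainHistory(checksums_before=model.prior_checksums())
    best_state = model.state_dict()

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = model.forward(train=True, rng=rng)
            loss = bce_with_logits_loss(ad.take_rows(logits, batch),
                                        Tensor(labels[batch]))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
            n_seen += len(batch)
        mean_loss = epoch_loss / max(n_seen, 1)
        history.loss.append(mean_loss)
        if mean_loss < history.best_loss:
            history.best_loss = mean_loss
            history.best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    history.checksums_after = model.prior_checksums()
    if history.checksums_after != history.checksums_before:
        raise RuntimeError("prior graph matrices were modified during training")
    return history


def predict(model: Model, protein_ids=None) -> np.ndarray:
    """Sigmoid scores in [0, 1]; dropout off. Rows follow `protein_ids`."""
    logits = model.forward(train=False).data
    scores = 1.0 / (1.0 + np.exp(-logits))
    if protein_ids is None:
        return scores
    index = {p: i for i, p in enumerate(model.protein_ids)}
    unknown = [p for p in protein_ids if p not in index]
    if unknown:
        raise DataError(f"unknown proteins: {unknown}")
    return scores[[index[p] for p in protein_ids]]


# ---------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------

def save_checkpoint(model: Model, path, history: TrainHistory | None = None) -> None:
    payload = {
        "config_json": np.array(json.dumps(asdict(model.config))),
        "protein_ids": np.array(model.protein_ids),
        "terms": np.array(model.terms),
        "a_f_raw": model.a_f_raw,
        "r_f": model.r_f,
        "r_b": model.r_b,
        "checksums_json": np.array(json.dumps(model.prior_checksums())),
    }
    for k, v in model.state_dict().items():
        payload[f"param::{k}"] = v
    for pid in model.protein_ids:
        payload[f"emb::{pid}"] = model.embeddings[pid]
    if history is not None:
        payload["loss_history"] = np.array(history.loss)
    np.savez(path, **payload)


def load_checkpoint(path) -> Model:
    with np.load(path, allow_pickle=False) as blob:
        config = ModelConfig(**json.loads(str(blob["config_json"])))
        protein_ids = [str(p) for p in blob["protein_ids"]]
        terms = [str(t) for t in blob["terms"]]
        diffusion = DiffusionPair(forward=blob["r_f"], backward=blob["r_b"])
        embeddings = {pid: blob[f"emb::{pid}"] for pid in protein_ids}
        model = Model(config, blob["a_f_raw"], diffusion, embeddings,
                      protein_ids, terms)
        state = {k[len("param::"):]: blob[k] for k in blob.files
                 if k.startswith("param::")}
    model.load_state_dict(state)
    return model
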