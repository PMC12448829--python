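"""Sequence-similarity network (SSN) construction and diffusion matrices.

Proteins become nodes of an undirected graph whose edges connect pairs
whose best BLAST E-value falls strictly below a threshold. Asymmetric
hits are symmetrized by taking the minimum E-value across directions.
Row-normalizing the (self-loop augmented) adjacency and its transpose
yields the forward/backward transition matrices used by the
bidirectional diffusion convolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

log = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class EvalueTable:
    """Directed (query, subject, e_value) rows with self-hits removed."""

    rows: pd.DataFrame  # columns: query, subject, evalue

    def __post_init__(self):
        required = {"query", "subject", "evalue"}
        if not required.issubset(self.rows.columns):
            raise DataError(f"EvalueTable needs columns {sorted(required)}")
        if (self.rows["evalue"] <= 0).any():
            raise DataError("e-values must be strictly positive")
        if (self.rows["query"] == self.rows["subject"]).any():
            raise DataError("self-pairs must be filtered before constructing EvalueTable")


@dataclass
class ProteinAdjacency:
    """Symmetric binary SSN adjacency with its E-value threshold."""

    matrix: np.ndarray
    threshold: float
    proteins: list

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DataError("protein adjacency must be square")
        if not np.array_equal(m, m.T):
            raise DataError("protein adjacency must be symmetric")
        if np.trace(m) != 0:
            raise DataError("protein adjacency has nonzero diagonal")
        if not np.isin(m, (0.0, 1.0)).all():
            raise DataError("protein adjacency entries must be binary")
        self.matrix = m

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


@dataclass
class DiffusionPair:
    """Row-normalized forward/backward transition matrices."""

    forward: np.ndarray
    backward: np.ndarray

    def __post_init__(self):
        for name, m in (("forward", self.forward), ("backward", self.backward)):
            m = np.asarray(m, dtype=float)
            if (m < 0).any():
                raise DataError(f"{name} diffusion matrix has negative entries")
            sums = m.sum(axis=1)
            ok = np.isclose(sums, 1.0, atol=1e-10) | np.isclose(sums, 0.0, atol=1e-12)
            if not ok.all():
                raise DataError(f"{name} diffusion rows must sum to 1 or be zero")


def read_blast_tabular(path, protein_ids, on_unknown: str = "error") -> EvalueTable:
    """Read BLAST outfmt-6 results into an :class:`EvalueTable`.

    Self-hits are dropped and duplicate directed pairs collapse to the
    minimum E-value. Unknown identifiers either raise (``on_unknown=
    "error"``) or are skipped with a log message (``"skip"``).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"BLAST tabular file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                         dtype={"qseqid": str, "sseqid": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path} as outfmt 6: {exc}") from exc
    if df.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 columns, found {df.shape[1]}")
    if df["evalue"].isna().any() or (pd.to_numeric(df["evalue"], errors="coerce").isna()).any():
        raise FormatError(f"{path}: non-numeric e-value column")

    known = set(protein_ids)
    mask = df["qseqid"].isin(known) & df["sseqid"].isin(known)
    if not mask.all():
        bad = pd.concat([df.loc[~mask, "qseqid"], df.loc[~mask, "sseqid"]])
        bad = sorted(set(bad) - known)
        if on_unknown == "skip":
            log.warning("skipping %d BLAST rows with unknown ids (e.g. %s)",
                        (~mask).sum(), bad[:3])
            df = df[mask]
        else:
            raise DataError(f"BLAST table references unknown protein ids: {bad[:5]}")

    df = df[df["qseqid"] != df["sseqid"]]
    # BLAST reports e-value 0.0 for extremely strong hits; clamp to a tiny
    # positive number so the strict-positivity invariant holds.
    evalues = df["evalue"].astype(float).clip(lower=np.nextafter(0, 1))
    pairs = pd.DataFrame({"query": df["qseqid"].values,
                          "subject": df["sseqid"].values,
                          "evalue": evalues.values})
    pairs = (pairs.groupby(["query", "subject"], as_index=False)["evalue"].min())
    return EvalueTable(rows=pairs)


def build_ssn(table: EvalueTable, threshold: float, protein_ids) -> ProteinAdjacency:
    """Threshold the E-value table into a symmetric binary adjacency.

    An edge {j, j'} exists iff the minimum directional E-value is
    strictly below `threshold`.
    """
    if threshold <= 0:
        raise ConfigError("E-value threshold must be > 0")
    protein_ids = list(protein_ids)
    index = {p: i for i, p in enumerate(protein_ids)}
    n = len(protein_ids)
    matrix = np.zeros((n, n))
    for query, subject, evalue in table.rows.itertuples(index=False):
        if evalue < threshold:
            i, j = index[query], index[subject]
            matrix[i, j] = matrix[j, i] = 1.0
    return ProteinAdjacency(matrix=matrix, threshold=threshold, proteins=protein_ids)


def row_normalize(matrix: np.ndarray) -> np.ndarray:
    """Divide each nonzero row by its sum; zero rows stay zero."""
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, matrix / sums, 0.0)
    return out


def diffusion_matrices(adj: ProteinAdjacency | np.ndarray,
                       add_self_loops: bool = True) -> DiffusionPair:
    """Forward/backward row-stochastic transition matrices from an adjacency.

    Self-loops (identity) are added before normalization by default.
    Zero-degree rows are left all-zero: isolated nodes propagate nothing.
    """
    matrix = adj.matrix if isinstance(adj, ProteinAdjacency) else np.asarray(adj, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DataError("adjacency must be square")
    base = matrix + np.eye(matrix.shape[0]) if add_self_loops else matrix
    return DiffusionPair(forward=row_normalize(base), backward=row_normalize(base.T))


def matrix_power_sequence(t: np.ndarray, n: int) -> list:
    """[t^1, t^2, ..., t^n] by repeated multiplication."""
    if n < 1:
        raise ConfigError("number of diffusion steps must be >= 1")
    t = np.asarray(t, dtype=float)
    powers = [t]
    for _ in range(n - 1):
        powers.append(powers[-1] @ t)
    return powers


def adjacency_to_edge_list(matrix: np.ndarray, ids) -> pd.DataFrame:
    """Upper-triangle edge list (id_a, id_b) of a symmetric binary adjacency."""
    ids = list(ids)
    rows = [(ids[i], ids[j])
            for i, j in zip(*np.nonzero(np.triu(matrix, k=1)))]
    return pd.DataFrame(rows, columns=["id_a", "id_b"])
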