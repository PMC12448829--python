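"""Deterministic synthetic-data generators.

Every external input the pipeline consumes has a generator here: a
rooted random DAG ontology, random amino-acid sequences, a sparse
symmetric E-value table, true-path-consistent labels and a
deterministic per-residue embedding stub standing in for the pretrained
language model. All generators are pure functions of their config
(seed included), so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, DataError
from .ontology import OntologyGraph
from .seqproc import AA_ALPHABET, DEFAULT_EMBED_DIM

EVALUE_LOG10_RANGE = (-30.0, -2.0)


@dataclass
class FixtureConfig:
    n_terms: int = 50
    n_proteins: int = 20
    seq_len_range: tuple = (20, 60)
    edge_density: float = 0.3
    annotation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1:
            raise ConfigError("n_terms must be positive")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        lo, hi = self.seq_len_range
        if lo < 1 or hi < lo:
            raise ConfigError("seq_len_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ConfigError("edge_density must be in [0, 1]")
        if not 0.0 <= self.annotation_rate <= 1.0:
            raise ConfigError("annotation_rate must be in [0, 1]")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def _protein_id(j: int) -> str:
    return f"P{j + 1:05d}"


def generate_toy_ontology(config: FixtureConfig) -> OntologyGraph:
    """Random rooted DAG over synthetic GO-style term ids.

    Node 0 is the root; every later node gets one uniformly chosen
    ``is_a`` parent among earlier nodes, plus extra is_a/part_of parents
    at a rate set by ``edge_density``. Parents always precede children
    in the index order, so the graph is acyclic by construction.
    """
    if config.n_terms < 2:
        raise ConfigError("toy ontology needs n_terms >= 2")
    rng = np.random.default_rng(config.seed)
    terms = [_term_id(i) for i in range(config.n_terms)]
    edges = []
    for i in range(1, config.n_terms):
        parent = int(rng.integers(0, i))
        edges.append((terms[i], terms[parent], "is_a"))
        if i >= 2:
            extra = rng.random(i) < config.edge_density / 4.0
            extra[parent] = False
            for p in np.nonzero(extra)[0]:
                rel = "part_of" if rng.random() < 0.3 else "is_a"
                edges.append((terms[i], terms[int(p)], rel))
    names = {t: f"toy term {t}" for t in terms}
    return OntologyGraph(terms=terms, edges=edges, names=names)


def generate_toy_proteome(config: FixtureConfig) -> list:
    """Random amino-acid sequences as Biopython SeqRecords with unique ids."""
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.seq_len_range
    alphabet = np.array(list(AA_ALPHABET))
    records = []
    for j in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[rng.integers(0, len(alphabet), length)])
        records.append(SeqRecord(Seq(seq), id=_protein_id(j), description=""))
    return records


def generate_evalue_table(config: FixtureConfig) -> pd.DataFrame:
    """Sparse symmetric E-value table (both directions emitted per pair).

    Each unordered pair is present with probability ``edge_density``;
    e-values are log-uniform over [1e-30, 1e-2] so threshold sweeps over
    1e-15..1e-5 partition the edges non-trivially.
    """
    if config.n_proteins < 2:
        raise ConfigError("e-value table needs n_proteins >= 2")
    rng = np.random.default_rng(config.seed + 2)
    lo_log, hi_log = EVALUE_LOG10_RANGE
    rows = []
    for j in range(config.n_proteins):
        for j2 in range(j + 1, config.n_proteins):
            if rng.random() < config.edge_density:
                evalue = 10.0 ** rng.uniform(lo_log, hi_log)
                rows.append((_protein_id(j), _protein_id(j2), evalue))
                rows.append((_protein_id(j2), _protein_id(j), evalue))
    return pd.DataFrame(rows, columns=["query", "subject", "evalue"])


def generate_labels(ontology: OntologyGraph, n_proteins: int,
                    config: FixtureConfig) -> np.ndarray:
    """Binary N_P x N_F label matrix, true-path consistent.

    Direct annotations are drawn per term at ``annotation_rate`` (with a
    floor of one term per protein) and then closed upward over
    ancestors, matching GO true-path semantics.
    """
    graph = ontology.to_networkx()
    rng = np.random.default_rng(config.seed + 3)
    terms = ontology.terms
    index = {t: i for i, t in enumerate(terms)}
    ancestors = {t: nx.descendants(graph, t) for t in terms}
    labels = np.zeros((n_proteins, len(terms)))
    for j in range(n_proteins):
        direct = np.nonzero(rng.random(len(terms)) < config.annotation_rate)[0]
        if direct.size == 0:
            direct = np.array([int(rng.integers(0, len(terms)))])
        for i in direct:
            labels[j, i] = 1.0
            for anc in ancestors[terms[i]]:
                labels[j, index[anc]] = 1.0
    return labels


class StubEmbedder:
    """Deterministic, weight-free stand-in for the pretrained embedder.

    Row t of the output is a pseudorandom function of (residue identity,
    position, seed) with values in [-1, 1], so embeddings are
    content-dependent, reproducible and positionally independent:
    changing residue t changes row t only.
    """

    def __init__(self, dim: int = DEFAULT_EMBED_DIM, seed: int = 0):
        if dim < 1:
            raise ConfigError("embedding dim must be positive")
        self.dim = dim
        self.seed = seed

    def _row(self, residue: str, position: int) -> np.ndarray:
        key = f"{residue}|{position}|{self.seed}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        return rng.uniform(-1.0, 1.0, self.dim)

    def __call__(self, seq: str) -> np.ndarray:
        if not seq:
            raise DataError("cannot embed an empty sequence")
        return np.stack([self._row(aa, t) for t, aa in enumerate(seq)])


def stub_embedder(seq: str, dim: int = DEFAULT_EMBED_DIM,
                  seed: int = 0) -> np.ndarray:
    """Functional form of :class:`StubEmbedder`."""
    return StubEmbedder(dim=dim, seed=seed)(seq)


# ---------------------------------------------------------------------
# writers for the standard on-disk formats
# ---------------------------------------------------------------------

def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_obo(ontology: OntologyGraph, path) -> None:
    """Minimal OBO: one [Term] stanza per term with id/name/is_a/part_of."""
    parents = {}
    for child, parent, rel in ontology.edges:
        parents.setdefault(child, []).append((parent, rel))
    lines = ["format-version: 1.2", ""]
    for term in ontology.terms:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.names.get(term, term)}")
        for parent, rel in parents.get(term, []):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations(labels: np.ndarray, protein_ids, term_ids, path) -> None:
    """TSV annotation table (protein_id, go_id), one row per positive."""
    rows = [(protein_ids[j], term_ids[i])
            for j, i in zip(*np.nonzero(np.asarray(labels)))]
    pd.DataFrame(rows, columns=["protein_id", "go_id"]).to_csv(
        path, sep="\t", index=False)


def write_blast_tabular(table: pd.DataFrame, path) -> None:
    """12-column outfmt-6 TSV; only qseqid/sseqid/evalue carry signal."""
    rng = np.random.default_rng(0)
    out = []
    for query, subject, evalue in table.itertuples(index=False):
        pident = round(float(rng.uniform(30, 100)), 1)
        length = int(rng.integers(30, 400))
        bitscore = round(-10.0 * np.log10(evalue), 1)
        out.append((query, subject, pident, length, 0, 0, 1, length, 1, length,
                    f"{evalue:.3g}", bitscore))
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, header=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "go_id"}.issubset(df.columns):
        raise DataError(f"{path}: annotation table needs protein_id and go_id columns")
    return df
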