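"""Ontology handling: OBO parsing, frequency-based term selection and the
directed function-graph adjacency.

The ontology is a rooted DAG over GO-style term identifiers. Only
``is_a`` and ``part_of`` edges are retained; other relationship types
and obsolete terms are dropped at parse time. The adjacency convention
is declared once and used everywhere in the package:

    matrix[i, i'] = 1  <=>  directed edge term_i -> term_i'
                            with term_i the child (more specific term).

Rows index the source (child) term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, FormatError

RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyGraph:
    """Directed acyclic term graph.

    Attributes
    ----------
    terms : list of str
        Term identifiers, in a stable order.
    edges : list of (child, parent, relation) tuples
        Directed edges, child -> parent, relation in {"is_a", "part_of"}.
    names : dict, optional
        Term id -> human-readable name.
    """

    terms: list
    edges: list
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.terms)
        for child, parent, rel in self.edges:
            if child not in known or parent not in known:
                raise FormatError(f"edge ({child}, {parent}) references unknown term")
            if rel not in RELATIONS:
                raise FormatError(f"unsupported relation {rel!r}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise FormatError("ontology graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, rel in self.edges:
            g.add_edge(child, parent, relation=rel)
        return g

    def ancestors(self, term: str) -> set:
        """All terms reachable from `term` by child->parent edges."""
        return nx.descendants(self.to_networkx(), term)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass
class FunctionAdjacency:
    """Binary child->parent adjacency restricted to a term selection."""

    matrix: np.ndarray
    terms: list

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DataError("function adjacency must be square")
        if not np.isin(m, (0.0, 1.0)).all():
            raise DataError("function adjacency entries must be binary")
        if np.trace(m) != 0:
            raise DataError("function adjacency has nonzero diagonal")
        self.matrix = m


@dataclass
class TermSelection:
    """Ordered subset of terms chosen by descending annotation count."""

    selected: list
    counts: dict


def parse_obo(path) -> OntologyGraph:
    """Parse a minimal OBO flat file into an :class:`OntologyGraph`.

    Recognized stanza lines: ``id``, ``name``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete``. Obsolete terms are
    excluded along with any edge touching them. A referenced term that
    is not defined anywhere in the file is a format error, as is a cycle.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"OBO file not found: {path}")

    stanzas = []
    current = None
    in_term = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line == "[Term]":
            current = {"id": None, "name": None, "obsolete": False, "parents": []}
            stanzas.append(current)
            in_term = True
        elif line.startswith("["):
            in_term = False  # typedef or other stanza: ignored
        elif in_term and current is not None and line and not line.startswith("!"):
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            if key == "id":
                current["id"] = value
            elif key == "name":
                current["name"] = value
            elif key == "is_a":
                current["parents"].append((value, "is_a"))
            elif key == "relationship":
                parts = value.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    current["parents"].append((parts[1], "part_of"))
            elif key == "is_obsolete" and value.lower() == "true":
                current["obsolete"] = True

    if not stanzas:
        raise FormatError(f"no [Term] stanzas in {path}")

    defined = {s["id"] for s in stanzas if s["id"]}
    kept = [s for s in stanzas if not s["obsolete"]]
    terms = [s["id"] for s in kept]
    names = {s["id"]: s["name"] for s in kept if s["name"]}
    obsolete = defined - set(terms)

    edges = []
    for s in kept:
        for parent, rel in s["parents"]:
            if parent not in defined:
                raise FormatError(f"term {s['id']} references unknown term {parent}")
            if parent in obsolete:
                continue  # edge into an obsolete term is dropped with it
            edges.append((s["id"], parent, rel))

    return OntologyGraph(terms=terms, edges=edges, names=names)


def select_terms(annotations: pd.DataFrame, ontology: OntologyGraph,
                 max_terms: int) -> TermSelection:
    """Rank terms by annotation count and keep the `max_terms` most frequent.

    Ties are broken by lexicographic term id so the selection is
    deterministic. An empty annotation table yields an empty selection
    with a warning.
    """
    if max_terms < 0:
        raise DataError("max_terms must be >= 0")
    if annotations.empty:
        warnings.warn("empty annotation table: empty term selection", stacklevel=2)
        return TermSelection(selected=[], counts={})
    known = set(ontology.terms)
    unknown = set(annotations["go_id"]) - known
    if unknown:
        raise DataError(f"annotation table references unknown terms: {sorted(unknown)[:5]}")
    counts = annotations.groupby("go_id")["protein_id"].nunique().to_dict()
    ranked = sorted(counts, key=lambda t: (-counts[t], t))
    return TermSelection(selected=ranked[:max_terms], counts=counts)


def build_function_adjacency(ontology: OntologyGraph,
                             selection: TermSelection) -> FunctionAdjacency:
    """Restrict the ontology's child->parent edges to the selected terms.

    Edges whose intermediate terms were not selected are *not*
    transitively closed: the adaptive attention is expected to recover
    such links during training.
    """
    missing = set(selection.selected) - set(ontology.terms)
    if missing:
        raise DataError(f"selection contains terms absent from ontology: {sorted(missing)[:5]}")
    index = {t: i for i, t in enumerate(selection.selected)}
    n = len(index)
    matrix = np.zeros((n, n))
    for child, parent, _rel in ontology.edges:
        if child in index and parent in index:
            matrix[index[child], index[parent]] = 1.0
    return FunctionAdjacency(matrix=matrix, terms=list(selection.selected))
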