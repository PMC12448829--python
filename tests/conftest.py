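import numpy as np
import pandas as pd
import pytest

from protfun import fixtures, ontology, protein_graph
from protfun import model as model_mod


@pytest.fixture
def small_config():
    return fixtures.FixtureConfig(n_terms=12, n_proteins=10,
                                  seq_len_range=(15, 40), edge_density=0.4,
                                  annotation_rate=0.3, seed=7)


@pytest.fixture
def toy_ontology(small_config):
    return fixtures.generate_toy_ontology(small_config)


def build_toy_dataset(n_terms=10, n_proteins=20, seed=42, embed_dim=32,
                      annotation_rate=0.25, edge_density=0.3,
                      evalue_threshold=1e-10):
    """Assemble every model input from the fixture generators."""
    config = fixtures.FixtureConfig(
        n_terms=n_terms, n_proteins=n_proteins, seq_len_range=(15, 40),
        edge_density=edge_density, annotation_rate=annotation_rate, seed=seed)
    onto = fixtures.generate_toy_ontology(config)
    labels = fixtures.generate_labels(onto, n_proteins, config)
    records = fixtures.generate_toy_proteome(config)
    protein_ids = [r.id for r in records]
    evalues = fixtures.generate_evalue_table(config)
    adjacency = protein_graph.build_ssn(
        protein_graph.EvalueTable(rows=evalues), evalue_threshold, protein_ids)
    diffusion = protein_graph.diffusion_matrices(adjacency)
    selection = ontology.TermSelection(selected=list(onto.terms), counts={})
    function_adj = ontology.build_function_adjacency(onto, selection)
    embeddings = {r.id: fixtures.stub_embedder(str(r.seq), dim=embed_dim)
                  for r in records}
    return {
        "config": config, "ontology": onto, "labels": labels,
        "records": records, "protein_ids": protein_ids,
        "adjacency": adjacency, "diffusion": diffusion,
        "function_adj": function_adj, "embeddings": embeddings,
    }


@pytest.fixture(scope="session")
def toy_dataset():
    return build_toy_dataset()


def micro_model(n_terms=4, n_proteins=5, seed=3, **overrides):
    """A minimal assembled model for gradient and invariant tests."""
    data = build_toy_dataset(n_terms=n_terms, n_proteins=n_proteins,
                             seed=seed, embed_dim=8)
    kwargs = dict(embed_dim=8, channels=4, attn_dim=3, n_steps=2, n_layers=1,
                  dropout=0.0, epochs=2, batch_size=8, seed=seed,
                  dilations=(1, 2))
    kwargs.update(overrides)
    config = model_mod.ModelConfig(**kwargs)
    model = model_mod.assemble_model(config, data["function_adj"],
                                     data["diffusion"], data["embeddings"],
                                     data["protein_ids"])
    return model, data


@pytest.fixture
def annotations_frame(toy_ontology, small_config):
    labels = fixtures.generate_labels(toy_ontology, small_config.n_proteins,
                                      small_config)
    rows = [(f"P{j + 1:05d}", toy_ontology.terms[i])
            for j, i in zip(*np.nonzero(labels))]
    return pd.DataFrame(rows, columns=["protein_id", "go_id"])
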