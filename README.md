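# protfun

Adaptive dual-graph convolutional protein function prediction.

`protfun` predicts GO-term annotations for proteins by combining two
graphs that are kept structurally intact throughout training:

- a **function graph** — the GO DAG (is_a / part_of edges) restricted to
  the most frequently annotated terms, driving a unidirectional N-step
  diffusion convolution;
- a **protein graph** — a sequence-similarity network thresholded from
  all-vs-all BLAST E-values, driving a bidirectional (forward/backward
  transition matrix) diffusion convolution.

Both priors are complemented by learned sparse top-k attention matrices
(per-row top-k retention + softmax) fused into the same diffusion sums,
so missing links can be learned without ever modifying the prior
adjacency (checksummed before/after training). Sequences are encoded by
a frozen per-residue embedder (a pluggable adapter; a deterministic stub
with the standard 1280-feature width ships for offline use) refined by
stacked dilated causal convolutions (kernel width 3, dilations 1/2/4/8,
receptive fields 3/7/15/31) with gated multi-scale aggregation and a
gated global/local fusion. Evaluation is protein-centric CAFA style:
threshold sweep, Fmax, ROC-AUC.

The network and its training loop are implemented on a small
reverse-mode autodiff engine over NumPy (`protfun.autodiff`), validated
by finite-difference tests — no deep-learning framework is required.

## Command-line workflow

```sh
# 1. synthetic inputs (OBO ontology, FASTA, annotation TSV, BLAST outfmt 6)
protfun fixtures --out-dir data --seed 42 --n-terms 30 --n-proteins 20

# 2. graphs: term selection + function adjacency, SSN from E-values
protfun build-graphs --obo data/ontology.obo --annotations data/annotations.tsv \
    --blast data/blast.tsv --fasta data/proteome.fasta \
    --evalue-threshold 1e-10 --max-terms 30 --out-dir graphs

# 3. train (config keys = ModelConfig fields; YAML)
protfun train --config config.yaml --graphs-dir graphs \
    --annotations data/annotations.tsv --fasta data/proteome.fasta \
    --out-dir run

# 4. predict + evaluate
protfun predict --checkpoint run/checkpoint.npz --out preds.tsv
protfun evaluate --predictions preds.tsv --truth data/annotations.tsv --out-dir eval
```

Every stage writes a `manifest.json` (config snapshot, input hashes,
seed, outputs) sufficient to re-run it bit-identically. Exit codes:
0 success, 2 config error, 3 data/format error, 4 runtime error.

Real data drops in at the same seams: any OBO ontology, any FASTA, any
12-column BLAST tabular file, and any embedder callable mapping a
sequence to an L x K matrix (e.g. a transformer protein language model)
in place of the stub.

## Layout

- `src/protfun/fixtures.py` — deterministic synthetic-data generators + format writers
- `src/protfun/ontology.py` — OBO parsing, frequency-based term selection, function adjacency
- `src/protfun/protein_graph.py` — BLAST table ingestion, SSN, diffusion matrices
- `src/protfun/seqproc.py` — embedder seam, truncation, DCC stack, gated fusion
- `src/protfun/attention.py` — correlation attention, sparse top-k normalization
- `src/protfun/graphconv.py` — adaptive diffusion graph convolution blocks
- `src/protfun/model.py` — assembly, BCE-with-logits loss, training, prediction, checkpoints
- `src/protfun/metrics.py` — threshold sweep, Fmax, ROC-AUC
- `src/protfun/oracles.py` — brute-force references used only by tests
- `src/protfun/autodiff.py` — minimal reverse-mode autodiff + Adam
- `src/protfun/cli.py` — the staged workflow
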