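# guidegraph

Guide-RNA editing-efficiency prediction from graphs that combine the
sequence backbone with predicted RNA secondary structure.

Each guide is converted into a graph: one node per nucleotide, *sequential*
edges between backbone neighbours, and *structural* edges between base-paired
positions (from dot-bracket input or a built-in base-pair-maximization
predictor). A three-stage graph regressor — per-node MLP, multi-head graph
attention, graph convolution, pooled regression head — is trained on
efficiencies on the 0–100 percent scale. The model is implemented directly on
NumPy/SciPy arrays with hand-written backpropagation (verified against
numerical gradients in the test suite), so everything is deterministic and
dependency-light.

## Modules

| module            | purpose |
|-------------------|---------|
| `structure_core`  | dot-bracket parsing/serialization, validation, Nussinov-style structure prediction, Vienna file I/O |
| `graph_builder`   | guide records, node features (one-hot / embedding files), typed-edge graph assembly |
| `gnn_model`       | the graph-attention regressor: init, train, predict, fine-tune, random hyperparameter search, checkpoints |
| `evaluation`      | Spearman/Pearson/MSE, k-fold and holdout splits, alignment-identity redundancy filtering, label-permutation test |
| `interpretability`| per-position attention importance (received / emitted / hub scores) |
| `synthetic_data`  | datasets with a planted efficiency function over sequence and structure |
| `cli_io`          | file formats and the `guidegraph` command-line interface |

## CLI

End-to-end on synthetic data:

```bash
guidegraph simulate --n 500 --seed 7 --out guides.tsv --structures guides.vienna
guidegraph train --input guides.tsv --checkpoint model.npz --seed 7 --epochs 40
guidegraph evaluate --input guides.tsv --checkpoint model.npz --out metrics.tsv
guidegraph predict --input guides.tsv --checkpoint model.npz --out preds.tsv
guidegraph permtest --predictions preds.tsv --labels guides.tsv --out perm.tsv
guidegraph explain --input guides.tsv --checkpoint model.npz --out profile.tsv
guidegraph filter-similar --test guides.tsv --train guides.tsv --out sim.tsv
guidegraph search --input guides.tsv --trials 5 --out trials.tsv
```

Every command writes a `<out>.run.json` provenance sidecar with the full
configuration and seeds; identical configs reproduce outputs byte-for-byte.

Input formats: tab/comma-delimited guide tables (`id`, `sequence`, optional
`efficiency`, optional dot-bracket `structure`), FASTA, Vienna-style
structure files, and per-id embedding-matrix text files (shape-header blocks)
for plugging in externally computed per-nucleotide embeddings.

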