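# duplexgnn

miRNA target prediction as graph classification: each miRNA–target-site
duplex is encoded as a small undirected graph whose nodes are nucleotide
triplet words embedded with CBOW word2vec, and classified by a graph neural
network (spectral convolution, sample-and-aggregate, or single-head
attention) with a global pooling readout and a fully connected softmax head.

Everything — CBOW training, the three message-passing layer families, a
minimal reverse-mode autodiff engine, Adam, plateau LR scheduling and early
stopping — is implemented in NumPy, so the package has no deep-learning
framework dependency.

## Layout

| module | role |
| --- | --- |
| `duplexgnn.sequence_encoding` | triplet tokenisation, per-corpus CBOW embedding tables (fitted on training splits only) |
| `duplexgnn.word2vec` | the CBOW trainer (negative sampling, mini-batch SGD) |
| `duplexgnn.duplex_graph` | duplex graph construction (chain edges + index-aligned cross edges) |
| `duplexgnn.gnn_classifier` | GCN / GraphSAGE / GAT layers, pooling, FC head; functional per-layer API and batched forward |
| `duplexgnn.training_eval` | stratified 0.7:0.15:0.15 splits, Adam training loop with plateau LR reduction and early stopping, BACC/precision/recall, multi-replicate orchestration with 95% CIs |
| `duplexgnn.synthetic_data` | planted seed-complementarity duplex generator (positives contain the DNA reverse complement of the miRNA seed region) |
| `duplexgnn.io_interface` / `duplexgnn.cli` | TSV / paired-FASTA I/O, results files, CLI |
| `duplexgnn._autodiff` | tape-based reverse-mode autodiff over NumPy arrays |

## CLI

```bash
# generate a synthetic dataset with a learnable planted signal
duplexgnn simulate --n-pairs 2000 --seed 1 --out data.tsv

# fit the two CBOW embedding tables on a training split
duplexgnn train-embeddings --dataset data.tsv --out-dir embeddings/

# train / evaluate / predict with a YAML run config
duplexgnn train --config run.yaml --out-dir ckpt/
duplexgnn evaluate --checkpoint ckpt/ --dataset data.tsv --out metrics.tsv
duplexgnn predict  --checkpoint ckpt/ --dataset data.tsv --out preds.tsv

# full multi-replicate experiment and an architecture sweep
duplexgnn replicates --config run.yaml --out-dir results/
duplexgnn ablate --config run.yaml --param L_GNN --values 1,2,3 --out-dir ablation/
```

A run config looks like:

```yaml
dataset: data.tsv
classifier: {e_gnn: GAT, l_gnn: 5, d_gnn: 256, l_fc: 2, d_fc: 128, p_h: ADD, r_d: 0.4}
training:   {max_epochs: 1000, initial_lr: 0.001, batch_size: 512, early_stop_patience: 100}
split:      {train_frac: 0.7, val_frac: 0.15, test_frac: 0.15, n_replicates: 30, base_seed: 0}
embedding:  {dimension: 16, window: 5, epochs: 100, negative: 5, min_count: 1}
```

The tuned reference architectures are `GCN 3/128/2/512/MAX/0.4`,
`GAT 5/256/2/128/ADD/0.4` and `SAGE 5/256/3/256/ADD/0.4`
(`E_GNN L_GNN/D_GNN/L_FC/D_FC/P_h/R_D`).

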