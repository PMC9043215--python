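# psngcn

Multi-omics cancer diagnosis on a patient similarity network, with a
densely connected graph convolutional classifier.

## The problem

Tumor/normal classification from a single omic view (expression,
methylation, or copy number) discards two things clinicians and
modellers both care about: the *complementarity* of the views, and the
*similarity structure* among patients. `psngcn` is for computational
biologists who want a complete, reproducible reference implementation of
the network-based route: fuse the views into one patient graph, compress
each view into a compact code, and classify every patient using both.

## The method

Three stages, each its own module:

1. **Patient similarity network** (`psngcn.snf`). Per view, a scaled
   exponential kernel affinity
   `W_ij = exp(−d²(x_i, x_j) / (α·γ_ij))`, where `γ_ij` averages the two
   patients' K-nearest-neighbor distances and their own distance. Two
   normalizations — full (`P`, row-stochastic) and local (`S`, restricted
   to K neighbors) — feed the cross-diffusion update

   `P⁽ʰ⁾ ← S⁽ʰ⁾ · mean_{k≠h} P⁽ᵏ⁾ · S⁽ʰ⁾ᵀ`

   iterated T rounds with re-normalization, then averaged and symmetrized
   into the fused network.

2. **Denoising autoencoders** (`psngcn.dae`). One per omic, trained to
   reconstruct the clean [0, 1]-scaled matrix from a masked copy (20% of
   entries zeroed), MSE loss, Adam at learning rate 0.01, 50 epochs,
   mini-batches of 8. The 300-dimensional codes of the three views are
   concatenated into the node-feature matrix.

3. **DenseGCN** (`psngcn.densegcn`). Graph convolution
   `h = ReLU(D̃^(−1/2)(A+I)D̃^(−1/2) · H · W)` with dense connectivity:
   each block consumes the concatenation of the input features and all
   previous blocks' outputs, which keeps a 10-layer stack trainable on a
   cohort of a few hundred patients. Transductive training (loss on
   training nodes only), 500 epochs, best-validation model selection;
   positive-class precision/recall/F1, accuracy and AUC on held-out test
   nodes, averaged over five repeats with re-randomized 60/20/20 splits.

`psngcn.preprocess` handles missingness filtering (strict 20% thresholds,
features before samples), sample intersection, mean imputation and min-max
scaling; `psngcn.synthetic_data` generates multi-view cohorts with a known
shared latent class structure for testing everything end to end;
`psngcn.pipeline` orchestrates the whole run, the repeats and the two
ablations (fused network vs identity adjacency; omic subsets).

## Worked example

Simulate a small cohort, then run the full pipeline from the shell:

```bash
psngcn simulate --n 120 --dims 300,300,360 --delta 4 --seed 7 --out cohort/
cat > config.yaml <<EOF
inputs: [cohort/rna.tsv, cohort/meth.tsv, cohort/cnv.tsv]
labels: cohort/labels.tsv
dae: {latent_dim: 32, hidden_dims: [64]}
repeats: 3
seed: 7
EOF
psngcn run-all --config config.yaml --out report.json
```

which prints (numbers from this exact invocation, abridged to 4 digits):

```json
{
  "per_repeat": [
    {"precision": 0.9231, "recall": 1.0,    "f1": 0.96,   "accuracy": 0.9583, "auc": 0.9931},
    {"precision": 1.0,    "recall": 0.8182, "f1": 0.9,    "accuracy": 0.9167, "auc": 1.0},
    {"precision": 1.0,    "recall": 0.9091, "f1": 0.9524, "accuracy": 0.9583, "auc": 1.0}
  ],
  "mean": {"precision": 0.9744, "recall": 0.9091, "f1": 0.9375,
           "accuracy": 0.9444, "auc": 0.9977}
}
```

Each repeat draws a fresh 60/20/20 split of the 120 patients (so each test
set has 24) and re-initializes every network; the `mean` block is the
five-number summary the method reports. On this strongly separated
synthetic cohort the label ranking is essentially exact (AUC ≈ 1): the two
or three misclassified patients per repeat are threshold misses, visible as
the precision/recall trade-off flipping between repeats. The same stages
are available individually (`psngcn preprocess`, `psngcn snf`, `psngcn
dae`, `psngcn train`, `psngcn ablate`) and as plain library calls.

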