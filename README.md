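# bis-impute

Dropout imputation for single-cell RNA-seq with a distribution-agnostic
optimal-transport autoencoder.

Droplet scRNA-seq measures each cell shallowly: many transcripts that are
present are never captured, so the count matrix is riddled with technical
zeros ("dropout") that mask real expression. Most imputation models assume
a parametric noise law (typically zero-inflated negative binomial). Bis
does not: it trains an encoder/decoder on the log-normalized matrix `X`
under a relaxed optimal-transport objective

    L = E‖X − X̃‖²₂ + λ·MMD²_imq(Q(Z), P(Z)) + β·KL(P(Y_agg) ‖ Q(X̃_agg))

where `X̃ = D(E(X))` is the reconstruction, `Q(Z)` the distribution of
encoder codes, `P(Z) = N(0, σ_z²I)` an isotropic Gaussian prior matched via
the maximum mean discrepancy with an inverse-multiquadratics kernel
`k(u,v) = C/(C + ‖u−v‖²)`, `C = 2·d_z·σ_z²`, and the optional last term
pulls the per-gene aggregate of the reconstruction toward the per-gene
aggregate of a matched bulk RNA-seq table (Kullback–Leibler divergence
between the two normalized mean-expression profiles). Defaults follow the
reference configuration: encoder [512, 128], bottleneck 32, decoder
[128, 512], λ = 0.01, β = 0.5, Adam at 1e-3, batch size 512.

The package is aimed at method developers and benchmarkers: alongside the
model it ships a Splat-style gamma–Poisson group simulator with logistic
expression-dependent dropout, a binomial-downsampling corruption, matched
pseudo-bulk generation, and the full evaluation-metric suite (gene-/cell-
wise Pearson panels, ARI/NMI/pair-counting Jaccard, cell-type and
batch-mixing silhouette scores, confusion metrics, rank-based AUC), all
implemented from their defining formulas and cross-checked against
brute-force oracles in the tests. Everything runs on plain numpy — the
network, its gradients, and Adam included. See `docs/methods.md` for the
model, the simulator's generative chain, and design notes.

## Worked example

Simulate a grouped dataset with known truth, corrupt it with logistic
dropout, train, and measure recovery:

```python
import numpy as np
import bis

params = bis.SimParams(n_cells=500, n_genes=200, dropout_mid=3.0, seed=42)
ds = bis.simulate_groups(params)
print(f"observed zero fraction: {ds.zero_fraction():.3f}")

obs = bis.filter_qc(ds.observed_counts,
                    bis.QCThresholds(min_genes_per_cell=0, min_cells_per_gene=3))
obs_log = bis.log1p_transform(bis.normalize_total(obs))
keep = np.array([ds.true_counts.col_ids.index(g) for g in obs.col_ids])
true_log = bis.log1p_transform(bis.normalize_total(ds.true_counts.subset(cols=keep)))

bulk = bis.synth_bulk(ds.true_counts, n_samples=3, noise_cv=0.1, seed=42)
bulk_log = bis.log1p_transform(bis.normalize_total(bulk))
_, bulk_log = bis.align_genes(obs_log, bulk_log)

cfg = bis.BisConfig(epochs=150, batch_size=256, seed=0, fill_zeros_only=True)
model, history = bis.train(obs_log, bulk_log, cfg)
print(f"total loss, first -> last epoch: "
      f"{history.total_loss[0]:.1f} -> {history.total_loss[-1]:.1f}")

imputed = bis.impute(model, obs_log, cfg)
_, _, before = bis.pcc_panels(true_log, obs_log.with_values(obs_log.values, "imputed"))
_, _, after = bis.pcc_panels(true_log, imputed)
print(f"gene-wise PCC vs truth: {before['gene_wise_mean']:.3f} -> {after['gene_wise_mean']:.3f}")
print(f"cell-wise PCC vs truth: {before['cell_wise_mean']:.3f} -> {after['cell_wise_mean']:.3f}")
```

Output:

```
observed zero fraction: 0.338
total loss, first -> last epoch: 2949.8 -> 279.7
gene-wise PCC vs truth: 0.224 -> 0.337
cell-wise PCC vs truth: 0.815 -> 0.928
```

A third of the entries were zeroed by the simulated dropout; after
training, the zero-filled imputation raises the mean per-gene correlation
with the uncorrupted truth from 0.22 to 0.34 and the mean per-cell
correlation from 0.82 to 0.93.

## Command line

```sh
bis simulate --out-dir sim/ --dropout-mid 3 --seed 7
bis impute --sc sim/observed_counts.tsv --bulk bulk.tsv --out imputed.tsv \
    --epochs 300 --seed 0
bis evaluate --reference sim/true_counts.tsv --test imputed.tsv --report report.json
```

Each command logs to stderr, embeds the resolved configuration and seed in
its output sidecars, and is byte-reproducible for a fixed seed.

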