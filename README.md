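# ziln — zero-inflated log-normal microbial association networks

Microbial abundance tables from shotgun metagenomics are compositional
(sequencing depth is arbitrary), heavily overdispersed, and dominated by
zeros — many of which are *structural*: the taxon is truly absent, not
merely unsampled. Naive correlation or Gaussian graphical-model analyses on
such tables recover spurious associations. `ziln` implements a latent
Gaussian model built for exactly this regime, together with seeded
simulators and an evaluation harness, for researchers who want to infer —
or benchmark inference of — sparse taxon–taxon association networks.

## The model

For sample *i* and taxa *j* = 1…*p*:

```
z_i  ~  N(mu, Sigma)                      latent Gaussian layer
a_ij =  1{z_ij > delta_j} · exp(z_ij)     abundances; zeros below delta_j
y_i  ~  Multinomial(N_i, a_i / sum(a_i))  observed counts at depth N_i
```

The association network is the support of `Sigma^-1`: zeros of the
precision matrix encode conditional independence. Inference proceeds by

1. a **zero-preserving clr**: nonzero counts are log-transformed and
   centered by the mean log over the row's *nonzero* entries; zeros stay
   zero. Unlike the pseudocount workaround this keeps the transform
   invariant to per-sample rescaling.
2. **marginal fits**: per taxon, `delta_hat_j` is the minimum transformed
   nonzero value, and `(mu_hat_j, sigma2_hat_j)` maximize the mixed
   likelihood with `Phi(delta_hat)` mass on the zeros.
3. **posterior-mean imputation**: each zero is replaced by the truncated
   normal mean `E[z | z <= delta_hat_j]`; observed values pass through.
4. **sparse structure inference** on the reconstructed latent matrix, by
   graphical lasso or Meinshausen–Bühlmann neighborhood selection, along a
   decreasing penalty path; edges are ranked by the penalty at which they
   first enter a support.

Accuracy is scored by AUPR against the ground-truth graph (true edges are
rare among all pairs, so precision-recall is the right lens), plus AUROC,
precision@k, per-feature Kolmogorov–Smirnov distances between count
tables, Newman assortativity, and top-k edge-set overlap between methods.

## Worked example

```python
from ziln import infer_network, pr_metrics, simulation1_dataset

graph, _, counts = simulation1_dataset("erdos_renyi", p=100, n=300, seed=3)
for mode in ("ziln", "none"):
    path, ranked = infer_network(counts, method="mb", transform_mode=mode)
    rep = pr_metrics(ranked, graph)
    print(f"{mode:>4} | AUPR={rep.aupr:.3f}  AUROC={rep.auroc:.3f}  "
          f"precision@50={rep.precision_at_k[50]:.2f}")
```

prints

```
ziln | AUPR=0.744  AUROC=0.975  precision@50=0.88
none | AUPR=0.342  AUROC=0.788  precision@50=0.64
```

i.e. on 300 samples of 100 taxa with a planted 100-edge graph, ranking
edges after posterior-mean imputation more than doubles the area under the
precision-recall curve relative to feeding the zero-inflated transform to
the same estimator directly, and 88 of the 100 top-50 edge slots per run
are true associations. The scripts in `examples/` walk through each
capability (simulation, transform + imputation, inference, benchmarking,
graph summaries) and print a line of interpretation with each number.

A CLI mirrors the pipeline for shell use:

```sh
ziln simulate --topology erdos-renyi --p 300 --n 100 --seed 1 --out sim/
ziln infer sim/counts.tsv --method mb --out path.json edges.tsv
ziln eval edges.tsv sim/truth.graphml --out report.json
ziln benchmark --p 100 --n 300 --replicates 10 --seed 1 --out bench/
```

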