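# rcsp — patient-specific root causal gene discovery

Complex diseases usually trace back to a handful of *root causal genes*:
the first expression changes, driven by genetic and environmental root
causes, that set the pathogenic cascade in motion. Downstream of those few
genes, nearly every transcript ends up correlated with the phenotype, so
correlation-style scores (differential expression, regression residuals)
cannot tell the initiating genes from the bystanders.

`rcsp` implements **Root Causal Strength using Perturbations (RCSP)**.
Model the biology as a structural equation model over latent expression
levels X̃ with mutually independent error terms E (each Eᵢ bundles the
unobserved root causes acting directly on gene i) and a phenotype Y. The
per-patient **root causal strength** of gene i is

    Φᵢ = | E(Y | Pa(X̃ᵢ), X̃ᵢ) − E(Y | Pa(X̃ᵢ)) |,

the magnitude of the conditional causal effect of Eᵢ on Y — computable
without ever recovering the error terms. Two practical obstacles are dealt
with head-on:

* **Measurement error.** Sequencing yields counts Xᵢ ~ Pois(X̃ᵢ·πᵢⱼ);
  conditioning on batch B (but not library size) suffices for conditional
  expectations as depth grows, so no depth normalization is applied.
* **Unknown graph.** The conditioning sets are *surrogate ancestors*
  recovered from a Perturb-seq screen: a knockdown shifts the marginal
  distribution of every descendant, detectable with a per-gene Welch
  t-test of knockdown vs control cells. Only this binary ancestor
  structure is transferred from the single-cell screen to the bulk cohort.

Φ is then estimated per patient by a pair of nonlinear regressions
(earth-style adaptive hinge splines by default, RBF kernel ridge as the
dense alternative), summarized per gene by the root-mean-square **D-RCS**,
contrasted with the correlational **D-SD** baseline, clustered across
patients with Ward's method, and exported as preranked `.rnk` files for
gene-set enrichment tools.

The package ships the full synthetic benchmark: a coupled bulk +
Perturb-seq simulator from one latent DAG, closed-form and forward
Monte-Carlo oracles for the true Φ, and the ANM / LiNGAM / univariate /
multivariate-regression comparators.

## Worked example

```python
import numpy as np
from rcsp import (sample_sem, simulate_bulk, simulate_perturbseq, oracle_rcs,
                  surrogate_descendants, surrogate_ancestors, rcs_scores,
                  ward_cluster, RegressorSpec)

sem = sample_sem(31, 2 / 29, seed=7)                   # 30 genes + phenotype
bulk, latent = simulate_bulk(sem, n_samples=200, seed=8)
screen = simulate_perturbseq(sem, cells_per_condition=200, n_batches=10, seed=9)

sets = surrogate_ancestors(surrogate_descendants(screen, alpha=0.05))
result = rcs_scores(bulk, sets, RegressorSpec(seed=0))
truth = oracle_rcs(sem, latent)

order = np.argsort(-result.drcs)[:5]
for i in order:
    true_drcs = np.sqrt(np.mean(truth.phi_true[:, i] ** 2))
    print(f"{bulk.gene_names[i]:>4s}  D-RCS={result.drcs[i]:.3f}  "
          f"oracle={true_drcs:.3f}  tau={truth.tau[i]:+.3f}")
print(f"r(phi, phi_true) = "
      f"{np.corrcoef(result.phi.ravel(), truth.phi_true.ravel())[0, 1]:.3f}")
print(f"clusters: k={ward_cluster(result.phi).k_selected}")
```

prints

```
 V22  D-RCS=0.887  oracle=0.821  tau=+1.471
 V19  D-RCS=0.383  oracle=0.373  tau=+0.687
 V14  D-RCS=0.247  oracle=0.121  tau=-0.237
 V13  D-RCS=0.195  oracle=0.000  tau=+0.000
 V21  D-RCS=0.000  oracle=0.000  tau=+0.000
r(phi, phi_true) = 0.882
clusters: k=2
```

The two genes with genuinely large root causal effects (τ is the total
effect of the gene's error term on Y) head the D-RCS ranking and their
estimated deviations track the closed-form oracle; genes with no directed
path to Y sit at or near zero, up to regression noise (V13). The
per-patient Φ matrix correlates 0.88 with the exact truth.

The same pipeline runs from the shell on TSV / Matrix Market files:

```sh
rcsp simulate --p 50 --n-bulk 200 --cells-per-condition 200 --seed 1 --out sim/
rcsp surrogates --mtx sim/perturb/matrix.mtx --features sim/perturb/features.tsv \
     --barcodes sim/perturb/barcodes.tsv --perturbations sim/perturb/perturbations.tsv \
     --out sa.tsv
rcsp rcs --bulk sim/bulk_counts.tsv --samples sim/bulk_samples.tsv \
     --surrogates sa.tsv --regressor splines --out scores/
rcsp cluster --phi scores/phi.tsv --k auto --out clusters/
rcsp run-all --config run.toml        # everything above in one step
```

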