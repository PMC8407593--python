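# bann — biologically annotated Bayesian networks for multi-scale GWAS

`bann` performs SNP-level association mapping and SNP-set (gene-level)
enrichment analysis *simultaneously*, for quantitative traits in genome-wide
association (GWA) studies.  It is aimed at statistical geneticists who want
interpretable posterior inclusion probabilities (PIPs) at both genomic
scales from one model fit, together with an estimate of the phenotypic
variance explained (PVE), from either individual-level genotypes or GWA
summary statistics.

## The model

Let **X** be an N × J matrix of allele dosages (0/1/2), **y** an N-vector
quantitative trait (both column-standardized), and {S₁, …, S_G} a list of
annotated SNP-sets — genes, and the intergenic regions between consecutive
genes.  The model is a partially connected Bayesian network regression

    y = Σ_g h(X_g θ_g + 1 b_g) w_g + 1 b,

where X_g collects the member SNPs of set g, h is a leaky ReLU
(h(x) = x for x > 0, 0.01x otherwise), θ are SNP-level weights and w are
SNP-set weights.  Sparsity-inducing priors act at both scales:

* input layer: θ_j ~ π_θ Σ_k η_k N(0, σ²_θk) + (1 − π_θ) δ₀, a K = 3
  normal-mixture spike-and-slab (large / moderate / small effects);
* hidden layer: w_g ~ π_w N(0, σ²_w) + (1 − π_w) δ₀.

Inference is variational EM with coordinate ascent, run over log-spaced
grids of π_θ ∈ [1/J, 1] and π_w ∈ [1/G, 1] and combined by importance
weights proportional to the exponentiated evidence lower bounds (Bayesian
model averaging).  The summaries are

    PIP(j) = Pr[θ_j ≠ 0 | y, X],     PIP(g) = Pr[w_g ≠ 0 | y, X, θ_g],

with the median-probability rule (PIP ≥ 0.5) as the selection criterion.
With only summary statistics available, the same machinery runs on the LD
matrix **R** as design and the marginal OLS effects θ̂ as response
(`BANNSummary`), exploiting E[θ̂] = **R**θ.

## Worked example

```python
import numpy as np
from bann import BANN, SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_individuals=2000, n_snps=2000, h2=0.6, rho=1.0, seed=7)
X, snp_map, mask, trait = simulate_dataset(cfg)   # sparse: 2 enriched sets

model = BANN(membership=mask, grid_size=10).fit(X, trait.y)
print("causal SNP PIPs:", np.round(model.pip_snp_[trait.causal_snps], 3))
print("enriched set PIPs:", np.round(model.pip_set_[trait.enriched_sets], 3))
print("PVE (snp, set): %.3f %.3f" % (model.pve_snp_, model.pve_set_))
print("SNPs selected at PIP>=0.5:", int((model.pip_snp_ >= 0.5).sum()))
```

Output:

```
causal SNP PIPs: [0.001 1.   ]
enriched set PIPs: [1. 0.]
PVE (snp, set): 0.599 0.582
SNPs selected at PIP>=0.5: 1
```

The trait has broad-sense heritability H² = 0.6 generated by two causal
SNPs; the stronger one is recovered with PIP 1.0 (the weaker effect is below
the detection limit at this sample size, so it is honestly left unselected),
its SNP-set is flagged as enriched, and the PVE estimates recover H² to
within about 0.01.

A command-line interface wires the same steps end to end:

```bash
bann simulate --n 2000 --snps 2000 --h2 0.6 --seed 7 --out sim/
bann fit --genotypes sim/genotypes.tsv --phenotype sim/phenotype.tsv \
         --mask sim/mask.tsv --snp-map sim/snp_map.tsv --out results/
bann evaluate --scores results/snp_pips.tsv --truth sim/truth_snps.tsv --out eval/
```

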