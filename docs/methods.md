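# Methods

## Model

The package fits a partially connected Bayesian network regression for a
standardized quantitative trait **y** on standardized allele dosages **X**:

    y = Σ_g h(X_g θ_g + 1 b_g) w_g + 1 b,    h(x) = x if x > 0, 0.01x otherwise.

Connectivity is fixed by the annotation mask: SNP j feeds hidden unit g iff
j ∈ S_g, where the SNP-sets S_g are genes (optionally buffered by ±b bp to
capture flanking regulatory variation) and the intergenic runs between
consecutive genes.  A SNP inside overlapping genes feeds every such unit with
the same weight θ_j.  The biases b_g, b are deterministic centering
constants; with column-standardized inputs they are zero and are reported as
such.

Priors encode sparsity at both scales.  SNP weights get a K = 3
normal-mixture spike-and-slab, θ_j ~ π_θ Σ_k η_k N(0, σ²_θk) + (1−π_θ)δ₀
with σ²_θ1 > σ²_θ2 > σ²_θ3, modelling large, moderate and small nonzero
effects; SNP-set weights get a single-slab spike-and-slab with probability
π_w.  Association evidence is summarized by posterior inclusion
probabilities, PIP(j) = Pr[θ_j ≠ 0 | y, X] and
PIP(g) = Pr[w_g ≠ 0 | y, X, θ_g]; the median-probability rule (PIP ≥ 0.5)
defines selection.

## Inference

The posterior is approximated by a fully factorized variational family; each
coefficient's factor is a (K+1)-outcome mixture with component inclusion
probabilities α_jk, component means μ_jk and variances s²_jk.  One
coordinate-ascent sweep refreshes every factor at its mean-field fixed
point,

    s²_jk = (xⱼᵀxⱼ/τ² + 1/σ²_θk)⁻¹,
    μ_jk  = (s²_jk/τ²) xⱼᵀ r_j            (r_j: residual excluding SNP j),
    α_jk  ∝ π_θ η_k (s_jk/σ_θk) exp(μ²_jk / 2 s²_jk),   spike ∝ 1 − π_θ,

maintaining the residual incrementally (O(NJK) per sweep; the sweep is a
numba kernel).  M-steps update τ² to the expected residual sum of squares
over N and each σ²_θk to its responsibility-weighted second moment, with the
decreasing order restored by jointly relabeling mixture columns.  Sweeps and
M-steps alternate until the evidence lower bound (ELBO) changes by less than
ε = 1e-4, with a cap of 10,000 sweeps; factors are initialized from prior
draws under a user seed, and refits under the same seed are bit-identical.
Because every step maximizes the same bound, the ELBO trace is
non-decreasing; the fitter raises an internal-consistency error if it ever
falls beyond float tolerance, and the test suite asserts monotonicity at
every grid point.

Training is two-stage.  The *inner* problem regresses y on X under the
mixture prior, iterated to convergence at each of L log-spaced values of
π_θ ∈ [1/J, 1] (L = 20 by default; the experiments below use L = 10, which
changes results negligibly in the strong-sparsity regimes exercised).
Per-grid fits are combined with importance weights softmax(ELBO_l), computed
through log-sum-exp.  The averaged posterior-mean weights m_θ define the
hidden activations H (columns h(X_g m_θg), mean-centered and standardized);
the *outer* problem then regresses y on H with the K = 1 machinery over a
π_w ∈ [1/G, 1] grid and is averaged the same way.  An ablation flag replaces
h by the identity (fully linear hierarchy); a second flag disables model
averaging and instead updates π in the M-step via the posterior odds
Σ_j PIP(j) vs Σ_j (1 − PIP(j)).

Two numerical guards matter in practice:

* **Slab floor.**  The σ²_θk M-step can collapse the smallest component
  toward zero, turning the slab into a second point mass; inclusion then
  costs nothing, π becomes unidentified and drifts to the top of its grid,
  and null PIPs inflate.  Slab variances are therefore floored at the
  single-predictor detection scale var(y)/mean(xⱼᵀxⱼ) (≈ τ²/N for
  standardized data).  The floor is fixed per fit, so M-steps remain
  constrained maximizers and monotonicity is untouched.
* **Hidden-unit gating.**  Enrichment of a set is the event that it contains
  at least one nonzero-effect SNP, and the set-level posterior is defined
  conditionally on the input layer.  A unit whose members carry essentially
  no posterior mass is a zero neuron: its pre-activation is shrinkage noise,
  and rescaling it to unit variance would manufacture a spurious in-sample
  predictor (the noise is built from xⱼᵀy and is therefore biased toward
  correlating with y).  A unit enters the outer regression only when
  1 − Π_{j∈S_g}(1 − PIP(j)) ≥ 0.5; gated-out sets report PIP(g) = 0.
  Under a permuted-phenotype null this leaves zero selections at both
  scales, while genuinely enriched sets (which by construction contain
  associated SNPs) are unaffected.

**PVE.**  Phenotypic variance explained is estimated as the ratio of the
empirical variance of the genetic predictor to that of the phenotype, in
expectation under the variational posterior:
E_q Var(Xθ) = Var(X m) + Σ_j (xⱼᵀxⱼ/N) Var_q(θ_j), grid-averaged; the
analogous quantity on H m_w gives the SNP-set-level estimate; both are
clipped to [0, 1].  Using the full posterior rather than the squared mean
avoids the PIP² shrinkage bias at intermediate inclusion probabilities.
PVE remains an in-sample estimate and is known to be underestimated for
epistatic and highly polygenic traits, where variational means are
over-shrunk.

## Summary-statistics mode

With D = {R, θ̂} (in-sample LD correlations and per-SNP OLS marginal
effects), the asymptotic identity E[θ̂] = Rθ turns the same model into a
regression of θ̂ on R: the design becomes R, the response θ̂ (used raw — the
residual variance absorbs its scale), and hidden units use the R_g columns.
Optional diagonal shrinkage (1−λ)R + λI is exposed for rank-deficient
external panels (default λ = 0).  With R = I the inner problem decouples
into exact per-SNP spike-and-slab posteriors, which the tests verify.

A caveat quantified during development: the summary-mode coordinate
statistic is the individual-level one multiplied once more by the *estimated*
R.  Estimation noise in R has magnitude ~1/√N per entry, and when J ≈ N its
aggregate effect on a null SNP's statistic matches the statistic's own
scale, so the *ranking of null SNPs* (not of true signals) genuinely
decorrelates between the two modes.  Rank concordance between modes is
therefore benchmarked at N ≫ J (N = 6000, J = 1000), the regime in which
in-sample summary statistics are a faithful compression of the data; there
the SNP-PIP Spearman correlation is 0.81–0.85 across seeds.

## Trait simulator

Synthetic genotypes are Binomial(2, MAF) dosages with MAF ~ U(0.05, 0.5)
i.i.d. across SNPs, on one synthetic chromosome at 1 kb spacing; options add
Balding–Nichols subpopulation structure (Beta-perturbed subpopulation
frequencies at divergence F_st) and block LD via an adjacent-copy mixing
weight.  Traits follow

    y = Σ_{c∈C} x_c θ_c + Wφ + ε,

with C the causal SNPs drawn from a few enriched SNP-sets (defaults: 1% of
sets enriched, 1% of their member SNPs causal — the sparse architecture;
10%/10% gives the polygenic one), W all pairwise products of causal-SNP
dosages, and θ, φ standard normal.  Components are mean-centered,
sequentially orthogonalized (interaction against additive, noise against
both) and rescaled by their realized variances so that the additive
component explains exactly ρH², the interaction component (1−ρ)H² and the
noise 1−H² of a unit total variance, per dataset.  The orthogonalization
implements the assumption that additive and non-additive genetic effects
are uncorrelated: the additive projection of the raw epistatic signal is
counted as additive variance, as in the classical variance-partition
definition.  Defaults H² = 0.6 and ρ = 1 (with H² ∈ {0.2, 0.6} and ρ = 0.5
as the standard alternatives) mirror the simulation settings the framework
is validated under.  A master seed spawns named substreams (genotypes,
selection, effects, noise), so every piece is independently reproducible.

What the simulator does *not* emulate: coalescent-realistic LD decay and
haplotype structure, rare variants, case-control ascertainment, and real
ancestry composition.  Passing tests therefore demonstrate correctness of
the inference machinery and calibrated behavior under the stated generative
model, not performance on real cohort data.

Desk-scale problem sizes used by the test suite — N = 2000, J = 2000–3000,
G ≈ 150–215, 20–50 replicates — are the package's standard validation
conditions; the concordance benchmark uses N = 6000, J = 1000 for the
reason above.

## Annotation construction

BED gene intervals (0-based half-open) are converted to 1-based inclusive;
SNP positions follow VCF convention.  Membership is inclusive at both
buffered ends; strand is ignored.  Unannotated SNPs form maximal per-
chromosome runs between consecutive (buffered, merged) gene blocks, named
`Left-Right` after the flanking genes (`chrStart-…`/`…-chrEnd` at ends).
Gene sets with a single member SNP are dropped and the SNP folded into the
surrounding intergenic run — no SNP is silently discarded; singleton
intergenic runs are merged into the nearest neighbouring run.  Intergenic
runs are recomputed against buffered gene spans; the buffer itself applies
to genes only.  Every constructed mask satisfies: each set has ≥ 2 members,
each SNP belongs to ≥ 1 set.

## Evaluation utilities

Selections are scored by empirical power and FDR (an empty selection has
FDR 0 by convention) with full ROC and precision–recall curves; Bayesian
scores use the median-probability cutoff and frequentist P-values a
Bonferroni-corrected α/m.

## Known limitations

* Variational PIPs are not perfectly calibrated; sparse solutions trade
  type-II for type-I error, and PVE is underestimated under epistasis and
  strong polygenicity.
* Set-level inference is conditional on the input layer: a set none of
  whose SNPs receives posterior mass cannot be flagged, by design.
* The intergenic-run naming assumes gene names are unique genome-wide;
  collisions across chromosomes are disambiguated by suffixing.
* Case-control traits, multi-layer (pathway) hierarchies and external
  reference-panel LD handling beyond diagonal shrinkage are out of scope.
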