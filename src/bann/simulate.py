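"""Synthetic genotype and quantitative-trait generation.

Traits are generated from the sparse architecture

    y = sum_{c in C} x_c theta_c + W phi + eps,

where C is the set of causal SNPs drawn from a small number of enriched
SNP-sets, W holds all pairwise (cis) interaction products between causal-SNP
dosage columns, and eps is Gaussian noise.  Components are rescaled against
their *realized* variances so that, per dataset, the additive part explains
rho * H^2, the interaction part (1 - rho) * H^2, and the noise 1 - H^2 of a
unit total phenotypic variance.  H^2 is the broad-sense heritability and rho
the additive fraction of it; rho = 1 is the purely additive limit.

Genotypes are drawn as Binomial(2, MAF) allele dosages, i.i.d. across SNPs,
with optional Balding-Nichols population structure and an optional
adjacent-SNP mixing weight that induces block LD.  A single master seed
spawns named substreams (genotypes / selection / effects / noise) so each
piece is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .annotation import AnnotationMask, GeneInterval, build_annotation_mask

__all__ = [
    "SimulationConfig",
    "SimulatedTrait",
    "simulate_genotypes",
    "select_causal",
    "simulate_trait",
    "simulate_covariate_structure",
    "tiling_gene_intervals",
    "simulate_dataset",
]

_STREAMS = ("genotypes", "selection", "effects", "noise", "structure")


@dataclass(frozen=True)
class PopulationStructure:
    """Balding-Nichols-style subpopulation divergence spec."""

    n_subpopulations: int = 2
    fst: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the sparse, highly heritable, purely additive scenario:
    1% of SNP-sets enriched, 1% of the SNPs inside them causal, H^2 = 0.6,
    rho = 1.  MAF range (0.05, 0.5) keeps simulated variants common, mirroring
    post-QC GWA panels.
    """

    n_individuals: int = 2000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.6
    rho: float = 1.0
    pct_enriched_sets: float = 0.01
    pct_causal_in_set: float = 0.01
    structure: PopulationStructure | None = None
    ld_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        for name in ("pct_enriched_sets", "pct_causal_in_set"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.ld_weight < 1:
            raise ValueError("ld_weight must be in [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, reproducible substream of the master seed."""
        i = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[i])


@dataclass
class SimulatedTrait:
    """A simulated phenotype with its exact variance decomposition."""

    y: np.ndarray
    causal_snps: np.ndarray
    enriched_sets: np.ndarray
    theta_c: np.ndarray
    phi: np.ndarray
    additive_component: np.ndarray
    interaction_component: np.ndarray
    noise_component: np.ndarray
    tau2: float

    def variance_shares(self) -> dict[str, float]:
        vy = float(np.var(self.y))
        return {
            "total": vy,
            "additive": float(np.var(self.additive_component)) / vy,
            "interaction": float(np.var(self.interaction_component)) / vy,
            "genetic": float(
                np.var(self.additive_component + self.interaction_component)
            )
            / vy,
            "noise": float(np.var(self.noise_component)) / vy,
        }


def simulate_genotypes(config: SimulationConfig):
    """Draw an N x J dosage matrix in {0,1,2} and a matching SNP map.

    Per-SNP MAFs are uniform on ``config.maf_range``.  With population
    structure, subpopulation frequencies are perturbed around the ancestral
    MAF by a Balding-Nichols Beta draw with divergence ``fst``.  With
    ``ld_weight`` > 0, each allele copy repeats the previous SNP's copy with
    that probability, producing decaying block correlation.  SNPs are laid on
    one synthetic chromosome at uniform 1 kb spacing.
    """
    N, J = config.n_individuals, config.n_snps
    if N < 2 or J < 2:
        raise ValueError("n_individuals and n_snps must both be >= 2")
    rng = config.rng("genotypes")
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=J)

    if config.structure is not None:
        P = config.structure.n_subpopulations
        fst = config.structure.fst
        groups = rng.integers(0, P, size=N)
        if fst > 0:
            a = maf * (1 - fst) / fst
            b = (1 - maf) * (1 - fst) / fst
            sub_maf = rng.beta(a[None, :], b[None, :], size=(P, J))
        else:
            sub_maf = np.broadcast_to(maf, (P, J)).copy()
        freq = sub_maf[groups]  # N x J per-individual frequency
    else:
        groups = None
        freq = np.broadcast_to(maf, (N, J))

    if config.ld_weight > 0:
        copies = np.empty((2, N, J), dtype=np.int8)
        for a_i in range(2):
            draws = (rng.random((N, J)) < freq).astype(np.int8)
            copies[a_i, :, 0] = draws[:, 0]
            for j in range(1, J):
                repeat = rng.random(N) < config.ld_weight
                copies[a_i, :, j] = np.where(repeat, copies[a_i, :, j - 1], draws[:, j])
        X = (copies[0] + copies[1]).astype(np.float64)
    else:
        X = rng.binomial(2, freq).astype(np.float64)

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(J)],
            "chromosome": "chr1",
            "position": 1 + 1000 * np.arange(J, dtype=np.int64),
        }
    )
    if groups is not None:
        snp_map.attrs["groups"] = groups
    return X, snp_map


def tiling_gene_intervals(
    snp_map: pd.DataFrame, snps_per_gene: int = 20, gap_snps: int = 8
) -> list[GeneInterval]:
    """Synthetic gene annotation tiling a simulated chromosome.

    Alternates gene blocks of ``snps_per_gene`` SNPs with unannotated gaps of
    ``gap_snps`` SNPs, so :func:`build_annotation_mask` yields gene and
    intergenic SNP-sets of realistic, comparable sizes.
    """
    genes = []
    pos = snp_map["position"].to_numpy()
    chrom = snp_map["chromosome"].iloc[0]
    j, g = 0, 0
    step = snps_per_gene + gap_snps
    while j + snps_per_gene <= len(pos):
        g += 1
        genes.append(
            GeneInterval(f"G{g:04d}", chrom, int(pos[j]), int(pos[j + snps_per_gene - 1]) + 1)
        )
        j += step
    return genes


def select_causal(mask: AnnotationMask, config: SimulationConfig):
    """Draw enriched SNP-sets and the causal SNPs within them.

    ceil(pct_enriched_sets * G) sets are drawn uniformly without replacement;
    causal SNPs are drawn uniformly from the union of their members, with the
    guarantee that every enriched set contains at least one causal SNP (the
    causal count is raised to the number of enriched sets when needed, and
    draws are repeated until coverage holds).
    """
    rng = config.rng("selection")
    G = mask.n_sets
    n_sets = int(np.ceil(config.pct_enriched_sets * G))
    if n_sets < 1:
        raise ValueError("requested number of enriched sets is zero")
    enriched = np.sort(rng.choice(G, size=n_sets, replace=False))
    union = np.unique(np.concatenate([mask.members(g) for g in enriched]))
    n_causal = max(n_sets, int(np.ceil(config.pct_causal_in_set * union.size)))
    if n_causal < 1:
        raise ValueError("requested number of causal SNPs is zero")

    member_sets = [set(mask.members(g)) for g in enriched]
    for _ in range(1000):
        causal = np.sort(rng.choice(union, size=n_causal, replace=False))
        cset = set(causal.tolist())
        if all(cset & ms for ms in member_sets):
            return enriched, causal
    # stratified fallback: one per set, then fill uniformly
    picks = {int(rng.choice(sorted(ms))) for ms in member_sets}
    rest = np.setdiff1d(union, np.fromiter(picks, dtype=np.int64))
    extra = rng.choice(rest, size=n_causal - len(picks), replace=False) if n_causal > len(picks) else []
    causal = np.sort(np.concatenate([np.fromiter(picks, dtype=np.int64), np.asarray(extra, dtype=np.int64)]))
    return enriched, causal


def _orthogonalize(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Project the (centered) component v off the span of earlier components."""
    for u in others:
        uu = u @ u
        if uu > 0:
            v = v - u * (u @ v) / uu
    return v


def _rescale(v: np.ndarray, target_var: float, label: str) -> np.ndarray:
    if target_var == 0:
        return np.zeros_like(v)
    realized = np.var(v)
    if realized <= 0:
        raise FloatingPointError(f"zero-variance {label} component before rescaling")
    return v * np.sqrt(target_var / realized)


def simulate_trait(
    X: np.ndarray,
    causal: tuple[np.ndarray, np.ndarray],
    config: SimulationConfig,
) -> SimulatedTrait:
    """Generate y = additive + pairwise-interaction + noise at unit variance.

    Effects theta_c and phi are standard normal; the additive component is
    rescaled to realized variance rho * H^2, the interaction component to
    (1 - rho) * H^2, and the noise to 1 - H^2.  Components are mean-centered
    and sequentially orthogonalized (interaction against additive, noise
    against both) before rescaling: additive and non-additive genetic
    effects are taken as uncorrelated, so the additive projection of the
    raw epistatic signal is counted as additive variance, and the realized
    decomposition Var(y) = rho*H^2 + (1-rho)*H^2 + (1-H^2) = 1 holds
    exactly for every dataset rather than only in expectation.  If an
    effect draw yields a degenerate (zero-variance) component, effects are
    regenerated from the next substream, up to 10 attempts.
    """
    enriched, C = causal
    C = np.asarray(C, dtype=np.int64)
    if C.size == 0 or C.max() >= X.shape[1]:
        raise ValueError("causal indices empty or out of range")
    use_epistasis = config.rho < 1
    if use_epistasis and C.size < 2:
        raise ValueError("rho < 1 requires at least 2 causal SNPs for pairwise interactions")

    N = X.shape[0]
    Xc = X[:, C]
    if use_epistasis:
        iu = np.triu_indices(C.size, k=1)
        W = Xc[:, iu[0]] * Xc[:, iu[1]]
    else:
        W = np.zeros((N, 0))

    eff_rng = config.rng("effects")
    noise_rng = config.rng("noise")
    var_add = config.rho * config.h2
    var_int = (1 - config.rho) * config.h2
    var_noise = 1 - config.h2

    last_err: Exception | None = None
    for _ in range(10):
        theta = eff_rng.standard_normal(C.size)
        phi = eff_rng.standard_normal(W.shape[1])
        eps = noise_rng.standard_normal(N)
        try:
            add_raw = Xc @ theta if config.h2 > 0 else np.zeros(N)
            add_raw = add_raw - add_raw.mean()
            inter_raw = W @ phi if var_int > 0 else np.zeros(N)
            inter_raw = _orthogonalize(inter_raw - inter_raw.mean(), [add_raw])
            eps_raw = _orthogonalize(eps - eps.mean(), [add_raw, inter_raw])
            add = _rescale(add_raw, var_add, "additive")
            inter = _rescale(inter_raw, var_int, "interaction")
            noise = _rescale(eps_raw, var_noise, "noise")
        except FloatingPointError as exc:
            last_err = exc
            continue
        y = add + inter + noise
        return SimulatedTrait(
            y=y,
            causal_snps=C,
            enriched_sets=np.asarray(enriched, dtype=np.int64),
            theta_c=theta,
            phi=phi,
            additive_component=add,
            interaction_component=inter,
            noise_component=noise,
            tau2=var_noise,
        )
    raise FloatingPointError(f"degenerate component after 10 attempts: {last_err}")


def simulate_covariate_structure(
    y: np.ndarray, X: np.ndarray, n_pcs: int, seed: int = 0
):
    """Add genotype-PC confounding to a phenotype.

    The top ``n_pcs`` principal-component score vectors of the column-
    standardized genotype matrix, each weighted by a standard-normal draw, are
    added to y; y is then re-standardized to zero mean and unit variance.
    Returns (y_new, pc_scores, weights).  ``n_pcs = 0`` is a no-op apart from
    the re-standardization.
    """
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    if n_pcs > min(X.shape):
        raise ValueError("n_pcs exceeds min(N, J)")
    y = np.asarray(y, dtype=np.float64)
    if n_pcs == 0:
        out = y - y.mean()
        return out / out.std(), np.zeros((len(y), 0)), np.zeros(0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(Xs)
    rng = np.random.default_rng(seed)
    weights = rng.standard_normal(n_pcs)
    out = y + scores @ weights
    out = out - out.mean()
    return out / out.std(), scores, weights


def simulate_dataset(
    config: SimulationConfig,
    snps_per_gene: int = 20,
    gap_snps: int = 8,
):
    """Convenience end-to-end draw: genotypes, annotation mask, and trait.

    Returns (X, snp_map, mask, trait)."""
    X, snp_map = simulate_genotypes(config)
    genes = tiling_gene_intervals(snp_map, snps_per_gene, gap_snps)
    mask = build_annotation_mask(snp_map, genes, buffer_bp=0)
    causal = select_causal(mask, config)
    trait = simulate_trait(X, causal, config)
    return X, snp_map, mask, trait
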